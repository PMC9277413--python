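"""The grain-size experiment: model accuracy versus quadrat side length.

Runs a reduced design (three scales, a few repetitions) and prints how the
median test R2 and rRMSE change with grain size, plus the minimum adequate
sampling scale under the R2 > 0.7 and rRMSE < 20% requirements.
"""

import pandas as pd

import scalewoods as sw

cfg = sw.SyntheticConfig(seed=1)
stems, grid = sw.generate_forest(cfg)
allometry = sw.AllometryTable.default()

frames = []
for side in (10.0, 100.0, 200.0):
    design = sw.SamplingDesign(side_min=side, side_max=side,
                               quadrats_per_scale=100, repetitions=5, seed=1)
    frames.append(sw.run_scale_experiment(stems, grid, design, allometry))
results = pd.concat(frames, ignore_index=True)

summary = sw.summarize(results)
cols = ["scale_m", "R2_median", "rRMSE_median", "MAE_median", "cat_Structure"]
print(summary[cols].round(3).to_string(index=False))

mas = sw.minimum_adequate_scale(summary)
print(f"\nminimum adequate scale: {mas if mas is not None else 'none qualified'}")
print("accuracy improves with grain size because fine-scale growth noise")
print("averages out within larger quadrats while terrain and stand structure persist.")
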