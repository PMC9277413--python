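"""Sample buffered quadrats at one grain size and build the 22-predictor
feature table.

Each row holds the topographic covariates (CE, SLC), seven species-diversity
indices, twelve stand-structure indices, the Reineke density index, and the
response P (AGB productivity, Mg/ha/yr) for one quadrat.
"""

import numpy as np

import scalewoods as sw

cfg = sw.SyntheticConfig(seed=1)
stems, grid = sw.generate_forest(cfg)
surface = sw.fit_kriging_surface(grid)
allometry = sw.AllometryTable.default()

rng = np.random.default_rng(0)
side = 50.0
quadrats = sw.sample_quadrats(cfg.plot_x, cfg.plot_y, side, n=100, rng=rng)
features = sw.build_feature_table(stems, quadrats, surface, allometry)

print(f"{len(features)} quadrats of {side:g} x {side:g} m")
print(features[["CE", "SLC", "Richness", "D1", "GiDBH", "SDI", "P"]]
      .describe().loc[["mean", "std", "min", "max"]].round(3).to_string())
print("\ncolumns:", ", ".join(features.columns))
print("P is the per-quadrat net biomass productivity the models predict.")
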