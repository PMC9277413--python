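# scalewoods

Grain-size dependence of forest above-ground-biomass (AGB) productivity
models on stem-mapped, twice-censused plots.

Forest inventories estimate AGB productivity — the net periodic annual
increment P (Mg ha⁻¹ yr⁻¹) of above-ground biomass — from sample quadrats.
The accuracy of models linking P to terrain, species diversity, stand
structure and stand density depends strongly on the quadrat size used.
`scalewoods` makes that dependence measurable: it resamples a mapped plot
with buffered random square quadrats across a series of side lengths
(10–200 m in 5-m steps), builds a 22-predictor feature row per quadrat, fits
a tuned random-forest regression

P = f(Topography, Diversity, Structure, Density)

per grain and repetition, and reports how the six accuracy criteria
(ME, MAE, MRE, RMSE, rRMSE, R²) and the relative variable importances change
with grain — including the smallest quadrat size whose median R² > 0.7 and
median rRMSE < 20%.

The package is aimed at forest ecologists and biometricians designing
sampling campaigns on large permanent plots, and it ships a seeded
synthetic-forest generator (clustered stem maps, Weibull diameters,
spatially correlated growth noise, kriged terrain) so the whole pipeline is
testable without field data.

Main pieces:

- `scalewoods.synthetic` — two-census stem maps and corner elevation grids;
- `scalewoods.biomass` — power-law allometry AGB = a·DBH^b and quadrat P;
- `scalewoods.sampling` — scale series and buffered quadrat placement;
- `scalewoods.topography` — ordinary kriging of elevation, quadrat slope and
  aspect, the composites CE = cos(ASP)·ln(E) and SLC = tan(SLO)·cos(ASP);
- `scalewoods.indices` — Hill numbers, evenness, ACE, Chao1, size-class
  Shannon/Simpson, Gini, CV, Weibull shape, lognormal skewness, Reineke SDI,
  and the 22-column feature assembly;
- `scalewoods.modeling` — Boruta screening, tuneRF-style mtry search, the
  OOB-stationarity ntree rule, 70/30 evaluation, permutation importances;
- `scalewoods.scale_analysis` — the experiment loop, per-scale medians,
  minimum-adequate-scale detection, CSV/plot export.

## Worked example

```python
import numpy as np, pandas as pd
import scalewoods as sw

cfg = sw.SyntheticConfig(seed=1)          # 500 x 600 m, two censuses, 5 yr
stems, grid = sw.generate_forest(cfg)
allometry = sw.AllometryTable.default()   # AGB_kg = 0.1 * DBH^2.4

frames = []
for side in (10.0, 100.0, 200.0):
    design = sw.SamplingDesign(side_min=side, side_max=side,
                               quadrats_per_scale=100, repetitions=5, seed=1)
    frames.append(sw.run_scale_experiment(stems, grid, design, allometry))
summary = sw.summarize(pd.concat(frames, ignore_index=True))
print(summary[["scale_m", "R2_median", "rRMSE_median", "MAE_median"]].round(3))
```

prints (examples/04_scale_experiment.py):

```
 scale_m  R2_median  rRMSE_median  MAE_median
    10.0     -0.028       166.296       2.108
   100.0      0.122        32.599       0.375
   200.0      0.418        13.113       0.129
```

Reading the numbers: at 10-m grain the fine-scale growth noise dominates a
quadrat, so the held-out R² is near zero and the rRMSE (RMSE as a percent of
mean observed P) is enormous — productivity measured on survey-size quadrats
is essentially unpredictable. By 200 m the noise has averaged out and the
persistent terrain and density signals remain, so the median R² rises to
≈ 0.4 and rRMSE falls to ≈ 13%. `sw.minimum_adequate_scale(summary)`
returns the smallest grain clearing R² > 0.7 and rRMSE < 20% (on this
synthetic plot no grain clears the R² bar, so it returns `None`).

A thin CLI wraps the same stages:

```sh
scalewoods generate --out data --seed 1
scalewoods run --stems data/stems.csv --elevation data/elevation.csv \
               --scales 10,50,100,140,200 --reps 10 --seed 1 --out results
```

`examples/` holds one short narrative script per capability.

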