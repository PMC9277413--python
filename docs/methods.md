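# Methods

## The question the pipeline answers

Forest above-ground-biomass (AGB) productivity — the net periodic annual
increment of AGB per unit area, P in Mg ha⁻¹ yr⁻¹ — is usually estimated
from sample quadrats far smaller than the stands they are meant to
represent. `scalewoods` quantifies how the grain size of those quadrats
changes both the attainable accuracy of productivity models and the
apparent importance of the predictors driving them, and from that derives a
minimum adequate sampling area.

The pipeline resamples a fully mapped two-census plot with square quadrats
whose side length runs from 10 m to 200 m in 5-m steps (39 grains). At each
grain, 100 quadrats are placed uniformly at random, with replacement,
inside the plot shrunk by a buffer of half the side length, so every
quadrat is fully contained. For each quadrat a 22-predictor feature row and
the response P are computed, and a tuned random-forest regression

    P = f(Topography, Diversity, Structure, Density)

is fitted and evaluated per repetition. Medians over repetitions summarise
each grain.

## Response and predictors

**P** is computed from species-specific power-law allometries
AGB_kg = a·DBH^b applied per census to live stems with DBH ≥ 5 cm;
P = (AGB₂ − AGB₁)/(area·interval). Both censuses use their own ≥ 5 cm
membership, so P is a *net* change: in-growth across the 5-cm threshold and
recruitment add, mortality subtracts, and P can be negative. All predictor
indices are computed on the same population (census-1 live stems,
DBH ≥ 5 cm) for internal consistency.

**Topography (2).** Corner elevations on a 20-m grid are interpolated by
ordinary kriging with an exponential semivariogram fitted by count-weighted
least squares and zero nugget, which keeps the surface an exact interpolator
at the corners. Per quadrat, E is the mean kriged elevation of the centre
and four corners; SLO is the mean inclination of the four planes through
each corner triple; ASP is the circular mean of the triples'
steepest-descent azimuths (clockwise from north; 0 by convention on flat
terrain). The model covariates are CE = cos(ASP)·ln(E) and
SLC = tan(SLO)·cos(ASP). The verbal definition of aspect as an angle
against "the vertical plane" is geometrically underdetermined; the
steepest-descent reading is used because it reduces to the standard DEM
aspect on planar terrain.

**Diversity (7).** Richness; Hill numbers D1 (exponential Shannon) and D2
(inverse Simpson); evenness E1 = ln(D1)/ln(S) (Pielou) and E2 = D2/S (the
printed source formulas are typographically ambiguous; these classical
forms are used, and both are simple enough to swap); the ACE estimator
(Chao & Lee, rare threshold 10, falling back to Chao1 when sample coverage
of the rare group is zero) and bias-corrected Chao1
S + F1(F1−1)/(2(F2+1)).

**Structure (12).** Stem count Nall; large-stem count N60 (DBH ≥ 60 cm);
skewness of the lognormal fitted to DBH by log-moments,
(e^{σ²}+2)√(e^{σ²}−1); the maximum-likelihood Weibull shape of DBH (profile
equation solved by bracketed root finding; degenerate inputs fall back
to 0); Shannon and Gini-Simpson diversity of 2-cm DBH classes and 1-m
height classes (left-closed bins anchored at 0); Gini coefficients of
per-stem basal area and of height with the forestry (n−1) normalisation;
coefficients of variation (population SD) of DBH and height in percent.

**Density (1).** Reineke's stand density index
SDI = (N/ha)·(Dg/20)^1.605 with Dg the quadratic mean diameter; the
reference diameter (20 cm) and exponent (Reineke's classical 1.605) are
configurable.

Degenerate quadrats (empty, single stem, constant values) take documented
fallback values of 0 rather than raising, so feature tables are always
complete; fallbacks are logged with the quadrat position.

## Modelling protocol

Per scale and repetition, on the quadrat feature table (n = 100):

1. A 70/30 train/test split is drawn first; everything before the final
   metrics sees only the training rows.
2. **Boruta screen.** Shuffled shadow copies of all still-active features
   are appended, a random forest is fitted, and features beating the best
   shadow importance score a hit; a two-sided binomial test (α = 0.05,
   ≤ 100 iterations) confirms or rejects. Tentative features are dropped;
   if fewer than two features are confirmed the screen falls back to all 22
   (logged). Importances in the screen are impurity-based.
3. **mtry.** A tuneRF-style search from round(p/3), stepping by factor 2
   while out-of-bag (OOB) error improves by more than 5%, returns the
   OOB-minimising value.
4. **ntree.** One ensemble is grown to 7000 trees recording the cumulative
   OOB mean-squared error at 500-tree checkpoints — the same error-vs-trees
   curve R's randomForest plots. The selected ntree is the first candidate
   whose forward difference falls below 0.1 (in squared response units),
   the threshold escalating by 0.05 until some candidate qualifies.
5. **Fit and evaluate.** The final model is the first-ntree-trees prefix of
   the grown ensemble (statistically identical to refitting, since bagged
   trees are i.i.d.). Test-set criteria: ME, MAE, MRE (signed,
   Σresid/Σobs), RMSE, rRMSE = 100·RMSE/mean(obs), and the standard R².
   Importances are permutation importances (MSE increase) on the test set,
   clipped at zero and normalised to percentages; screened-out features
   carry 0. Category importances sum member features over
   {Topography, Diversity, Structure, Density}.

The ensemble is an explicit bagging loop over scikit-learn regression trees
(`min_samples_leaf=5`, matching R randomForest's regression nodesize;
`max_features=mtry`), which exposes the cumulative OOB curve cheaply and
keeps every repetition fully seeded and reproducible.

**Summaries.** Per-scale medians (and SDs) over repetitions, plus median
|ME| and |MRE|. Because a median of sums is not the sum of medians, the
per-category importance medians are renormalised to 100% at each scale so
exported category curves conserve total share. The minimum adequate scale
is the smallest grain with median R² > 0.7 and median rRMSE < 20%.

## The synthetic plot

The analysis is demonstrated and tested on a seeded generator emulating a
30-ha (500 × 600 m) temperate mixed forest censused twice, five years
apart — the real analogue would be a stem-mapped permanent plot with
DBH ≥ 1 cm census thresholds and surveyed 20-m corner elevations.
Components, each a minimal textbook model:

- **Elevation:** base 680 m plus a long-wavelength sinusoidal trend and a
  Gaussian random field with exponential covariance (range 150 m), scaled
  so the realised relief is roughly ±100 m (≈ 580–800 m).
- **Community:** 20 species with geometric-series abundances (k = 0.15);
  stems clustered by a torus-wrapped Thomas process (mean 20 offspring per
  parent, 15-m Gaussian dispersal) at 0.1 stems/m²; DBH from a Weibull
  (shape 1.2, scale 12 cm) truncated at 1 cm; heights from
  H = 1.3 + 1.5·DBH^0.7.
- **Growth:** five-year increment g0·DBH^g1·exp(−g2·BA_local)·f(elev)·e^ε
  with (g0, g1, g2) = (0.5, 0.4, 0.3), BA_local the neighbour basal area
  within 10 m, f(elev) = exp(0.2·(680 − z)/100), and ε a zero-mean Gaussian
  field with correlation range 15 m and SD 0.4. Defaults give a 5-year
  increment of ≈ 1.3 cm for an isolated 10-cm stem and whole-plot
  P ≈ 1.4 Mg ha⁻¹ yr⁻¹, typical of temperate old growth.
- **Demography:** Bernoulli mortality with 5-yr base probability 0.05
  increasing in local crowding; recruits at 0.01 stems/m² entering at
  1–5 cm DBH.

The short-range growth noise is the scientifically load-bearing choice: at
10-m grains one noise patch dominates a quadrat and P is nearly
unpredictable, while at 200-m grains ≈ 180 independent patches average out
and the persistent terrain and density signals remain. That is what makes
model accuracy improve with grain size on synthetic data, mirroring the
behaviour expected of real plots.

What the generator does **not** emulate: species-specific silvics beyond a
±10% seeded jitter of the default allometric coefficients, crown
dimensions, broken or resprouted stems, directional disturbance, and
measurement error. Passing tests therefore demonstrate that the pipeline
recovers scale-dependence from data with the assumed statistical structure,
not that any particular real forest has that structure.

## Numerical choices and problem sizes

- Kriging exactness at data corners is machine-precision by construction
  (zero nugget); planar fields are reproduced within 0.05 m away from the
  plot margin. A constant elevation field short-circuits to a constant
  predictor instead of a degenerate variogram fit.
- The Weibull profile-likelihood root is bracketed in [0.01, 100] on
  mean-scaled data; ties and tiny samples fall back to 0.
- Aspect is reported as 0 when mean slope < 1e-6 degrees; circular
  averaging uses unit-vector means.
- Quadrat membership is half-open, so disjoint tilings partition stems
  exactly; centres are continuous uniform draws (no grid snapping).
- Headline experiments in the tests and the reproduction script use the
  desk-scale design — grains {10, 50, 100, 140, 200} m, 100 quadrats per
  grain, 10 repetitions — chosen as the smallest design in which the
  grain-size trends are stable across master seeds; the full 39 × 1000
  design of the sampling module is available through the same API and CLI.
- All randomness flows from integer seeds through `numpy` SeedSequences;
  per-repetition seeds derive from (design seed, scale, repetition), so
  results are independent of execution order and identical across runs.

## Known limitations

- On the default synthetic plot the median R² at 200 m is ≈ 0.4–0.6, so the
  minimum-adequate-scale rule (R² > 0.7, rRMSE < 20%) may return "none
  qualified"; the rule itself is exercised by construction in tests. Real
  plots with stronger environmental gradients can clear both thresholds.
- Boruta on an all-relevant definition will occasionally confirm a feature
  that is only chance-correlated with the response in-sample; no
  multiple-testing correction is applied (α = 0.05 per feature), matching
  the reference implementation's plain mode.
- Ordinary kriging with an exponential variogram slightly smooths sharp
  ridgelines; curvature-type terrain covariates are out of scope.
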