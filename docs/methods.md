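# Methods

This note documents the statistical models, the synthetic data the package is
validated on, and the numerical and design choices a maintainer should know.

## Seasonal occurrence model

Each seasonal subset (winter = {12, 1, 2}, spring = {3, 4, 5}, June–November
individually; the pooled bins exist because single winter/spring months hold
too few presences to model alone) is treated as a balanced binary
classification of presences against pseudo-absences. The model is a
logit-link binomial GLMM with fixed linear and quadratic effects per
environmental variable and a year random intercept:

    logit p_ij = x_ij' beta + u_j,    u_j ~ N(0, sigma^2)

**Estimation.** The marginal likelihood integrates the year intercepts out
per year-group with *adaptive* Gauss–Hermite quadrature (default 21 nodes):
nodes are recentred at each group's posterior mode (found by a concave 1-D
Newton iteration) and rescaled by the curvature there. Non-adaptive rules are
inaccurate here because a group with hundreds of observations makes the
integrand far narrower than the prior-scaled node spacing. The objective is
maximised over (beta, log sigma) with L-BFGS-B using the posterior-weighted
score as gradient (node placement contributes only at quadrature-error order).
The implementation is cross-checked in the test suite against direct numerical
integration and against `lme4::glmer(..., nAGQ = 25)` on a frozen dataset
(coefficients agree to ~1e-3, AIC to 4 decimals).

**Standardisation.** Covariates are z-scored internally; the constants are
stored in the fitted model and reused at prediction time, and coefficients are
reported on both scales.

**AIC and fallbacks.** AIC = 2k − 2·logLik with k counting all fixed effects
plus the variance parameter. With a single year level, or when the variance
estimate collapses below 1e-4 (common on the synthetic data, where year
effects act through the environment rather than on top of it), the model
falls back to a plain logistic regression via statsmodels GLM with the
`fallback` flag set and k excluding the variance.

**Selection.** Backward elimination under marginality: candidate moves demote
a quadratic variable to linear or drop a linear-only variable; the move with
the lowest AIC is applied while it improves the current AIC. Selection runs
independently per replicate dataset; the per-subset frequency table counts, in
how many of the five replicates each variable survives. Term sets are selected
once per dataset and then held fixed across CV folds — a mildly optimistic but
standard shortcut.

**Validation.** Stratified 5-fold CV; held-out rows are scored with the
population-level prediction (random intercept at its mean 0, since validation
folds may contain unseen years). AUC is the tie-aware Mann–Whitney statistic.
Threshold rules: fixed 0.5 (score ≥ 0.5 is presence); the observed-score
threshold minimising |sens − spec| (ties resolved toward the lower threshold);
and the largest observed threshold keeping sensitivity ≥ 0.95.

## Pseudo-absence sampling

Both samplers draw one pseudo-absence per presence inside a closed 500-km
buffer (planar Euclidean distance on synthetic grids, haversine on geographic
ones), excluding every presence cell of the same seasonal subset, and inherit
the presence's (year, month) so covariates come from matching layers. Within a
replicate set each (cell, year, month) is used at most once — the same key
occurrence thinning enforces; different sets are independent draws.

RSEP trains one one-class SVM per seasonal subset (RBF kernel, nu = 0.1,
sklearn `gamma="scale"`, inputs z-scored with presence statistics) on the
subset's presence covariates. Per presence, 30 uniform candidate cells are
scored; similarity is the sign of the decision function (inlier = 1,
outlier = 0) and one similarity-0 candidate is chosen at random. If ten
candidate redraws all fail, the sampler scans the entire eligible pool before
raising, so the error means exactly "no contrasting environment within the
buffer". The collinearity screen runs on RS datasets (RSEP needs a variable
set to profile on, which would be circular).

## Synthetic landscape and virtual species

The generator emulates monthly environmental stacks at a desk scale: default
60 × 60 grid of 25-km cells over 3 years, ~150 presences per month pooled
across years (~1 800 total). Each base variable (MINTEMP, PRECIPI, EVAPO,
NDVI) is a sinusoidal seasonal cycle plus a linear latitudinal gradient, a
static smooth spatial texture, a small per-year offset and i.i.d. noise;
MAXTEMP and VAPOR are derived from MINTEMP and EVAPO with noise calibrated so
the within-layer Pearson correlation hits a target (default r = 0.9,
reproducing the |r| ≥ 0.8 screen); the crop layer RFD is non-negative, zero
outside the May–October growing season, and stored for a single replicated
year like an average cultivation map. Gradients and textures are deliberately
strong enough that every 500-km buffer contains clearly contrasting
environments — a property of any real continental study region and a
prerequisite for one-class profiling to be well posed.

The default virtual species has a logistic occurrence probability with
bell-shaped responses (the same family the models fit, so parameter recovery
is well posed): minimum-temperature optimum 28 °C — above the mid-summer
landscape mean, making the species cold-limited so its suitable range expands
June → July/August and contracts in September like a migratory pest — with
broad secondary responses to NDVI (optimum 0.7) and evapotranspiration
(120 mm), peak logit 2.0 and detection rate 0.8. Occurrences are drawn
without replacement with probability proportional to suitability × detection,
giving at most one record per (cell, month, year).

**What the generator does not emulate:** spatial sampling bias, observation
error in covariates, true absences, dispersal limitation and source–sink
dynamics, skewed (non-quadratic) response shapes, and year effects beyond an
additive environmental offset. Passing tests therefore demonstrate that the
pipeline recovers a known niche under its own model family and honest
sampling — not that the model family is adequate for any particular real
dataset.

## Niche dynamics

The available environment pools, per (year, month), every cell within 500 km
of that month's presences; a 2-axis PCA of the z-scored pooled background
defines the niche space. Occurrence and background densities are Gaussian
KDEs (Silverman bandwidth) on a 100 × 100 grid spanning the pooled background
score range; occurrence densities are normalised to integrate to 1.
Backgrounds larger than 20 000 rows are subsampled (seeded) before the KDE,
whose cost scales with n_samples × n_grid. The analog mask keeps cells where
both periods' background densities exceed 1e-3 of their maximum; each
period's occupied niche keeps the densest cells holding 95 % of its density
mass. Stability, expansion (= 1 − stability) and unfilling are cell-count
ratios inside the mask.

A sampling property worth knowing: with two *independent* finite samples from
the same distribution, the binarised occupied regions differ at their
boundaries, so stability plateaus around 0.88–0.95 rather than 1.0 (measured
across bandwidths, grid resolutions and sample sizes up to ~900 per period).
Identity-level stability is reached only for literally identical density
grids. The tests therefore check the scientifically meaningful contrast — a
season-constant environment gives stability ≥ 0.8 and clearly above the
seasonal landscape's — rather than stability = 1 under resampling.

## Numerical choices and conventions

* Cells are half-open; boundary points belong to the lower-left cell.
  Row 0 is the southernmost row; cell ids are row-major.
* No-data cells carry NaN and are excluded from screening, map averages and
  regional (TEA) means.
* Rescaling: block mean for continuous variables, optional area-conserving
  sum for the crop layer; bilinear interpolation for refinement.
* The screen averages Pearson matrices arithmetically across the replicate
  datasets of a bin; constant columns get r = 0 with a warning. Removal is
  iterative, dropping from each offending pair the variable earliest in the
  configured priority list (default: VAPOR, MAXTEMP — the derived variables),
  so the outcome is independent of column order.
* Response-curve optima use partial dependence with other covariates at their
  training means; a vertex outside the variable's landscape range, or a
  monotone response, returns the maximising endpoint with a boundary flag, and
  boundary optima still enter the OEA average.
* Suitability maps average across years and across the month's replicate
  sub-models; interval classification is floor(10·v) capped at bin 9.
* All randomness flows from explicit seeds; the pipeline derives per-stage
  seeds from the master seed by hashing stage names, so stages rerun in
  isolation reproduce identical outputs.
* Serialisation is NetCDF (xarray, scipy backend) for rasters and CSV/JSON for
  tables; geographic CRS support is limited to a planar/geographic flag that
  switches the distance function.

## Known limitations

* One random-effect level (year) only; no spatial random effects or
  spatial-block CV, so autocorrelated data will look over-confident.
* Unpenalised logistic fits can see quasi-separation on strongly profiled
  (RSEP) datasets; coefficients grow large but AIC comparison and ranking
  remain usable.
* The niche indices depend on bandwidth, grid resolution and the occupancy
  threshold; defaults follow the conventional framework but absolute values
  should be compared only across analyses run with identical settings.
* Geographic-mode support covers distances and buffers, not reprojection.
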