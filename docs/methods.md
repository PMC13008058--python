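# Methods

`beetlephen` re-creates, on synthetic data with known truth, a complete
weather-and-landscape analysis of Colorado potato beetle (*Leptinotarsa
decemlineata*) population dynamics: thermal-time accumulation, inference of
generation structure, landscape composition around sampled fields,
seasonal feature construction, multiclass abundance modelling with
permutation importance, and varying-coefficient Poisson GAMM scenario
prediction. This note documents the models, the generative study
conditions, the numerical choices, and what the tests do and do not show.

## Degree days

Daily development is the area between a lower threshold L = 11 °C and the
day's temperature trace, modelled as one sine period through (tmin, tmax),
with temperatures above U = 31 °C counted at U (single sine, horizontal
cutoff). The six analytic cases are the standard Baskerville–Emin case
analysis; a numerical quadrature of the clipped sine serves as the
independent oracle in tests (agreement ≤ 1e-6 °C·day). One sine period
represents one day (no half-day splicing with the next day's tmin).
Accumulation starts at a January 1 biofix and resets each calendar year;
leap days are included. Flat days (tmin = tmax) are handled as the clipped
constant limit without touching the arcsin branches.

## Generation structure from counts

Counts are regressed (Poisson, log link) on year fixed effects plus one
coefficient per 25-CDD bin. The bin block is ridge-shrunk toward the
seasonal mean — the "random effect" treatment of the degree-day axis —
with the ridge strength chosen by generalized cross-validation on the
binned fit. The centred bin coefficients are then smoothed by a cubic
smoothing spline weighted by each coefficient's precision (≈ √ of the
count mass in its bin), with the classic residual-consistent smoothing
target s = m; precision weighting matters because early- and late-season
bins hold few, mostly zero counts and would otherwise produce spurious
wiggles. Landmarks are read off the smooth: first negative→positive
crossing = start of colonization, local maxima (prominence ≥ 5% of the
curve range, positive values only) = generation emergence peaks, minima
between consecutive peaks = generation breakpoints, last
positive→negative crossing = season end. Periods partition [0, ∞)
half-open: winter/spring before colonization, one interval per
generation, fall/winter after the last boundary. When only one interior
breakpoint exists (a clean two-generation season), the second generation
closes at season end. Landmark boundaries are global, not per-year.

## Landscape metrics

Rasters are categorical grids on a flat planar coordinate system (no CRS;
buffers are small relative to Earth curvature). Eleven cover classes:
potato, corn, soybean, wheat, legume, other cereals, forage, other crop,
water, developed, semi-natural. Within a 1-km circular buffer
(cell-centre-in-circle membership) the package computes per-class area
(ha), class-total perimeter:area ratio (4-connectivity edges, buffer and
raster boundaries count as edges; all patches of a class pooled —
per-patch averaging is an alternative convention the source description
does not resolve), Euclidean distance from the site to the nearest potato
cell centre (unbounded by the buffer), and Shannon diversity over buffer
class proportions. Buffers clipped by the raster edge are rejected rather
than computed partially. All metrics are tested against brute-force
enumeration.

## Seasonal features

Per site-year and period: medians of tmin, tmax, soil temperature, VPDmin,
VPDmax; total precipitation; means of solar radiation and snow-water
equivalent. Precipitation is a seasonal *sum* (the magnitudes of the
quantity as used downstream are only consistent with sums, despite
"mean total precipitation" phrasing appearing in places). Days map to
periods through their CDD. Because spring emergers entered the soil the
previous autumn, fall/winter aggregates attach to the *following* year;
the first simulated year is consumed as the lag donor. Correlated
predictors are pruned greedily: while any pair has |Pearson r| > 0.7,
drop from the worst pair the variable with the larger mean absolute
correlation (deterministic, ties by column order; zero-variance columns
dropped first). Retained columns are z-scored (n−1 denominator) with
statistics from the training partition only — fitting on all data risks
leakage; this is configurable. Percentiles use linear interpolation
between order statistics.

## Abundance classes and boosted trees

Counts per site/day are labelled Low / High / VeryHigh by the 25th/75th
percentiles of the pooled stage distribution (10th/90th for the
zero-inflated egg counts). Data are split 75/25, stratified by class.
The xgboost engine is tuned over a 30-point Latin hypercube on five
hyperparameters (trees 50–500, min child weight 1–10, depth 2–8, learning
rate 0.02–0.3 log-scaled, loss reduction 0–5) with 10 stratified folds,
ranked by macro one-vs-rest AUC. Reported metrics: argmax accuracy, macro
one-vs-rest AUC (trapezoidal), and the multiclass Brier score as the
per-observation sum of squared probability errors (range 0–2 — a
convention to keep in mind when comparing against 0–1-scaled variants).
Importance is permutation-based (shuffle one column, model fixed, loss =
multiclass cross-entropy with probabilities floored at 1e-15), averaged
over 50 permutations and evaluated on the test partition. A drop-and-refit
estimator would answer a different (and costlier) question. Note that for
a pure-noise column the permutation average within one fitted model is a
fixed quantity; its null distribution is across data realizations, which
is how the test suite evaluates it.

## Varying-coefficient Poisson GAMM

For one life stage: log E[count] = β₀ + γ·(year − ȳ) + Σ_v [β_v·v +
f_v(CDD)·v] + f₀(CDD) + b_site. Smooths use cubic B-spline bases with
second-order difference penalties (P-splines) and sum-to-zero constraints
over the observed data; basis dimensions 9 (main CDD smooth) and 10
(interactions) give reference degrees of freedom 8 and 9. Site intercepts
b_site form an identity-penalized ridge block (Gaussian random effect;
variance = 1/λ_site). Fitting is penalized IRLS with step halving; one
smoothing parameter per smooth plus one for the site block is chosen by
maximizing the Laplace-approximate restricted marginal likelihood (REML),
optimized by L-BFGS-B on the log scale with warm-started inner fits.
Uncertainty uses the Bayesian posterior covariance (X'WX + S_λ)⁻¹;
effective degrees of freedom are the block sums of diag[(X'WX+S)⁻¹X'WX].
Smooth-term p-values use a rank-⌈EDF⌉ Wald statistic on the smooth
coefficients (a pragmatic approximation; simulation shows it slightly
conservative under the null). One test cross-checks the fitter against R
mgcv (REML) on the year trend, site SD and fitted linear predictor —
bases differ, so coefficient-by-coefficient comparison is not defined.
The egg response stays plain Poisson despite simulated zero inflation;
the misfit surfaces in diagnostics and is deliberate.

Scenario prediction holds every covariate at its normalized mean (0) and
the site effect at its zero mode, sets the focal covariate to the 10th /
50th / 90th percentile of its raw values (converted through the stored
mean/sd), predicts the response-scale curve over the observed CDD range
for each sampling year, and averages the curves across years on the
response scale. The 95% band is built on the link scale for the
year-averaged linear predictor, then exponentiated; because averaging
exponentials exceeds exponentiating the average (Jensen), the mean curve
can sit slightly above the band centre when the year trend is strong.

## Synthetic study conditions

The generator emulates a Wisconsin-like potato region. Weather: one
regional daily series (seasonal sinusoid, mean 10.5 °C, amplitude
16.5 °C, AR(1) noise φ = 0.7, σ = 3 °C) plus per-site jitter; diurnal
range N(10, 2) °C; precipitation Bernoulli(0.3) wet days × Gamma(0.6, 12)
mm (≈ 800 mm/yr); VPD from the Tetens saturation curve at tmin/tmax minus
a shared actual vapour pressure (wetter days more humid); snow-water
equivalent accumulates on subfreezing days with instant melt otherwise;
soil temperature (7–28 cm analogue) is damped exponential smoothing of
air temperature. A season accumulates ≈ 1700–2200 CDD. The land cover is
a seeded nearest-seed tessellation (contiguous patches, ~200 cells each)
targeting a rotation-landscape mix (10% potato, 22% corn, 20%
semi-natural, …), realized within a few percentage points.

Counts follow log λ = α + phen_stage(CDD) + Σ[β_v + f_v(CDD)]·v +
γ·(year − y₀) + b_site with Poisson sampling; eggs additionally zeroed
with probability π = 0.5. Default phenology: adult humps at 500 and 1400
CDD, Gaussian on the log scale with widths 200/220 and heights 2.5/2.1.
The widths make the generations overlap, as the field system does: with
narrow non-overlapping humps the inter-generation valley is a wide flat
region at zero and "the breakpoint" stops being a well-defined landmark,
so overlap is a condition for the segmentation task to be meaningful, not
a convenience. Larval humps lag adults by +120 CDD (egg-to-first-instar
development time); egg humps by +50 CDD. Weekly scouting runs from the
first date with CDD ≥ 150 to the first with CDD ≥ 2200 (or the end of
accumulation). Covariate effects act through built-in generative
covariates (buffer potato area, summer median tmax, spring precipitation;
z-scored) with defaults β = 0.25, 0.20, −0.10, year trend γ = 0.05,
site SD σ = 0.35.

What the generator does **not** emulate: spatial correlation of weather
between sites beyond the shared regional series, year-specific land cover
(one static raster), management/insecticide effects, sweep-efficiency
observation error (counts are plain integers, not per-25-sweep averages),
and missing visits. Passing tests therefore demonstrate correctness of
the algorithms under a faithful but idealized data-generating process,
not robustness to real scouting data's messiness.

## Problem sizes and defaults

The default end-to-end configuration runs 60 sites × 3 years (the first
year feeds the fall/winter lag), a 12 × 12 km raster at 30 m cells, the
full 30-candidate × 10-fold tuning protocol, and a single life stage
(consumer = adults + larvae; others are one config switch away) — sizes
chosen so a complete run with all model fitting finishes in a few minutes
on one core while keeping every protocol parameter at its study value.
Recovery studies in the test suite use 100 sites × 3 years (phenology
landmarks) and 500 site-years (GAMM coverage, 100 replicate fits).

## Known limitations

- REML here is the Laplace/PQL-style approximation; for very low counts
  its smoothing-parameter estimates can differ from exact-likelihood
  implementations.
- Smooth p-values are approximate (rank-⌈EDF⌉ Wald); treat near-threshold
  significance with caution.
- The ridge-binned phenology profile assumes bins are exchangeable a
  priori; a fully Bayesian random-walk prior over bins would share
  information between neighbours before smoothing rather than after.
- P:A ratio pools all patches of a class; per-patch means would differ on
  fragmented classes.
- Scenario bands ignore smoothing-parameter uncertainty.
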