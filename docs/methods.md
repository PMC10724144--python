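# Methods

## Problem and scope

Satellite aerosol optical depth (AOD) is the only daily, globally gridded
proxy for surface PM2.5, but clouds, snow and swath geometry leave roughly a
third of land cell-days without a retrieval, and AOD itself must be
translated into surface concentration through meteorology and emissions.
This package implements the full chain that turns partially observed AOD
plus covariates into *gapless* daily PM2.5 fields and downstream health
statistics:

1. **Satellite-view merging** — two daily AOD views of the same truth
   (morning/afternoon overpasses) are combined; the second view is mapped
   onto the first's scale by an ordinary-least-squares conversion line
   fitted over coincident cell-days, and coincident cells take the
   unweighted mean of the two.
2. **AOD gap filling** — a space-time extra-trees model is trained on the
   merged *observed* AOD against spatially complete predictors (CTM AOD,
   meteorology, terrain, vegetation, space-time terms) and predicts every
   unobserved cell-day. Observed values pass through bit-exact; every value
   carries an origin flag (observed/predicted).
3. **PM2.5 retrieval** — quality-controlled daily station means are
   colocated with the gapless AOD and auxiliary covariates; one model spans
   the whole grid and year and predicts PM2.5 on every cell-day.
4. **Validation battery** — unit-holdout cross-validation (sample, station,
   1° grid cluster, state, day, ISO week, month, continent-stratified),
   "within" R², and permutation-importance attribution.
5. **Health impact** — WHO guideline exceedance, population weighting,
   log-linear acute mortality burden, and stringency-index lockdown-window
   differencing.

Everything runs on a seeded synthetic world; no external data is required.

## The space-time encoding

Tree ensembles handle longitude poorly (wrap-around at ±180°, latitude-
dependent metric). Each row therefore carries six derived features:

* `st_x, st_y, st_z` — the unit-sphere map `x = cos φ cos λ, y = cos φ sin λ,
  z = sin φ` (φ latitude, λ longitude, radians). Euclidean distance in
  (x, y, z) is a monotone function of great-circle distance, so random
  splits on these axes partition space coherently across the antimeridian
  and poles.
* `st_tsin, st_tcos, st_tlin` — day-of-year mapped onto the unit circle,
  `θ = 2π(d−1)/P` with `P` the period (365 or 366), plus a linear
  days-since-epoch term. The circle makes late December adjacent to early
  January; the linear term keeps distinct dates distinguishable over
  multi-year spans (the triple is injective), giving a helix.

A triangle-wave reading of the periodic term would satisfy the same
adjacency and injectivity properties; the sinusoidal form is the package's
canonical choice and is isolated in `st_encoding` so an alternative could be
swapped in without touching other modules.

## The learning core

Both stages use extremely randomized trees (scikit-learn's
`ExtraTreesRegressor`; split thresholds drawn at random, no bootstrap).
Defaults: 100 trees, minimum leaf size 2, all features eligible per split,
fixed seed. The wrapper (`stet_model`) owns the testable contract:
determinism under a fixed seed, a recorded feature manifest enforced at
prediction, refusal of missing/non-numeric predictors, and predictions
bounded by the training-target range (ensembles of leaf means cannot
extrapolate — this also guarantees non-negative PM2.5 given non-negative
targets; it is asserted, never clamped).

Two runtime-motivated deviations from the 100-tree default, fixed before any
skill numbers were read: the gap-fill stage uses 40 trees with leaf size 5
and subsamples at most 150 000 of the observed cell-days for training (the
default 40×80×365 grid has ~750 000), and the cross-validation batteries use
60 trees (8 schemes × 10 folds of refitting). Extra-trees accuracy plateaus
well below these sizes on desk-scale tables.

## Station quality control

Per station, in order: negatives → missing; runs of identical values longer
than 3 *continuous* hours → missing (run length ≥ 4 at exactly hourly
spacing; any time gap or removed value breaks a run); values strictly above
the station's 99.9th-percentile → missing. The percentile is the `higher`
order-statistic sample quantile, i.e. an attained value — only values
strictly above it are cut, so a short clean record never loses its own
maximum (with the interpolated quantile the maximum of any untied record
would always be removed). Rows are never deleted, only masked. A UTC day
yields a daily mean iff ≥ 20% of 24 hours are valid (≥ 5 hours; the
denominator is always 24). `to_utc` shifts integer-hour local offsets.

Grid harmonization: finer-than-target fields are block-averaged over target
cells; coarser fields are bilinearly interpolated at target cell centers
(clamped to the source hull, so complete sources yield complete outputs).
Cell bounds are half-open, left/bottom-inclusive — a station on a shared
edge belongs to exactly one cell.

## The synthetic world

The generator emulates the statistical structure the pipeline assumes, with
every parameter recorded in `WorldBundle.meta`:

* **Grid and calendar** — default 40×80 cells at 0.5°, centred on the
  equator (both hemispheres exist), one real-calendar year (365 days, 2021;
  366/2020 when leap). Multi-year scenarios are composed from single-year
  bundles (different seed, optional `pm_scale` multiplier emulating e.g.
  lockdown emission reductions).
* **AOD truth** — a smooth spatial base field (Gaussian-filtered noise)
  plus a seasonal harmonic whose phase flips by π between hemispheres plus
  a smooth space-time anomaly; clipped positive.
* **PM2.5 truth** — the documented closed form
  `pm = scale · clip(β₁·aod·(1+β₂·rh)·(pblh_ref/max(pblh, pblh_min))
  + β₃·emissions + A·season + ε, 0)` with β₁ = 55, β₂ = 1, β₃ = 20,
  pblh_ref = 800 m, pblh_min = 200 m, A = 6 µg/m³. The process noise ε has
  sd = 0.5·`noise_sd` (half the hourly instrument noise; `noise_sd` = 0
  gives an exactly deterministic truth for parameter-recovery tests).
  The aerosol term scales AOD by humidity growth and dilutes it by
  boundary-layer depth — the standard first-order physics of the
  AOD–PM2.5 relationship.
* **Satellite views** — terra = truth + small noise; aqua = 0.9·terra +
  0.05 + noise. The cloud mask is a smoothed 3-D random field thresholded
  at its `missing_frac` quantile (spatially and temporally coherent gaps,
  which stress gap filling far more than i.i.d. missingness). Each view has
  extra view-specific gaps, constructed disjointly so the *merged*
  missingness equals the cloud mask exactly and the realized missing
  fraction matches the configured target.
* **CTM fields** — truth block-averaged to a coarse grid, multiplied by a
  smooth bias field, offset, and bilinearly regridded back: spatially
  complete, right on average, wrong in detail.
* **Stations** — placed with probability proportional to population
  (uneven density, as in real networks), jittered within their cells.
  Hourly series = daily truth × (1 + 0.1·cos diurnal) + N(0, noise_sd);
  the diurnal factor averages to exactly zero over 24 h, so noiseless daily
  means reproduce the truth. Outliers (negatives, stuck runs of 4–8
  identical values, ×8–15 extremes) are injected at configured rates with
  mutual clearance, and every injected index is logged so QC recall is
  measurable exactly.
* **Regions, SI, BMR** — countries tile the grid into contiguous
  rectangles, subdivided into states and grouped into ~3 continents.
  Each country gets a stringency-index year (ramp–plateau–ramp, maximum
  40–95, or below 20 for a ~15% minority with no lockdown) and a baseline
  mortality rate drawn uniformly from 0.005–0.012 deaths person⁻¹ yr⁻¹.

**What a green test does not establish:** the world's PM2.5 is genuinely a
smooth function of the supplied predictors, so model skill here bounds
nothing about real-data skill; real aerosol chemistry, vertical profiles,
snow masking, instrument drift, and reporting artifacts are absent. The
synthetic tests establish that the *pipeline machinery* is correct
(contracts, pass-through, fold discipline, formulas), and that skill
*orderings* behave as spatiotemporal statistics predict.

## Validation conventions

`r2` is the squared Pearson correlation between observations and held-out
predictions (the scatter-plot convention); `1 − SSE/SST` is also computed as
`r2_ss`. NRMSE is RMSE divided by the mean of observations. Folds partition
the *unit* set (stations, days, 1° clusters, states, ISO weeks, calendar
months) as evenly as possible, deterministically under a seed; pooled
metrics over the concatenated held-out predictions are primary, per-fold
metrics reported alongside. Continent-stratified CV builds a separate
station-unit k-fold inside each continent. "Within" R² removes additive
station and year effects from both series by iterated two-way demeaning
(tolerance 1e-10; equivalent to dummy-variable regression residuals) before
correlating; zero residual variance yields NaN with a warning. Permutation
importance is the mean held-out RMSE increase over column shuffles, floored
at zero and normalized to percent; group contributions sum member percents.

## Health-impact conventions

* Exceedance is **strict** (`> 15/25/37.5/50/75 µg/m³`); days exactly at a
  threshold do not count. Missing days leave both numerator and denominator.
* "Populated" means density strictly above 1 person/km²; area fractions are
  over populated cells only, for ≥ 1/7/30 exceedance days.
* The exposure-response function is log-linear, `RR(C) = exp(β·max(C−c0,0))`
  with `β = ln(1.0065)/10` per µg/m³ (95% CI slopes from 1.0044/1.0086) —
  the standard short-term form consistent with a per-10 relative risk.
  The counterfactual `c0` defaults to 0; absolute burdens therefore depend
  on `c0` and are labelled as such, while period *differences* cancel it.
* Burden per cell-day: `MB = (RR−1)/RR · POP · BMR/N` with `N` the days in
  the year (366 in leap years); gridded population is rescaled per country
  to reported totals before use.
* The lockdown window is the maximal contiguous interval containing the
  (earliest) stringency-index argmax on which SI ≥ 0.5·max(SI), provided
  max(SI) surpasses 20. The 0.5 plateau fraction is a free parameter: the
  verbal rule ("most significant escalation and decline") is not
  operational, and this reading is isolated behind `plateau_frac`.

## Numerical choices and degenerate inputs

* OLS merge coefficients use closed-form normal equations; a constant
  second view over the overlap raises an insufficient-overlap error.
* Correlations over constant series are reported as NaN with a warning,
  never an exception (degenerate variance is a data property, not a bug).
* Sample quantiles in QC use the `higher` method (see above); all other
  quantiles are NumPy defaults.
* Ties in the SI argmax resolve to the earliest day.
* Seeds: every stochastic component (world generation, fold shuffling,
  training subsampling, permutation repeats) flows from an explicit integer
  seed; identical seeds give bit-identical outputs.

## Known limitations

* The gap-fill skill ceiling is set by how much of the AOD anomaly the
  coarse CTM field carries; with heavy missingness (80%) skill degrades but
  does not collapse, which the tests assert as an ordering, not a value.
* One model spans the whole grid and period (no per-region or per-day
  models); the space-time terms carry the heterogeneity. Real global
  products may shard for memory reasons; that engineering is out of scope.
* Station hourly records live in a single synthetic time zone; UTC
  alignment is exercised through configurable per-station offsets rather
  than a time-zone database.
* Absolute mortality burdens at `c0 = 0` count deaths attributable to *all*
  ambient PM2.5 and are reported only as labelled illustrative totals; only
  period differences are decision-grade within this package.
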