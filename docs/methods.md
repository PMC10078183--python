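# Methods

This note records the models, the synthetic study conditions, the
numerical choices, and the known limitations of `biastree`.

## The observation model

The package treats gridded occurrence data as the outcome of two
stacked processes on a regular grid of square cells (1 km by default):

* **Ecology.** True abundance in cell *i* is negative binomial,
  `N_i ~ NB(mu_i, theta)` with `log(mu_i) = x_i'beta`, where `x_i`
  collects an intercept, centred-and-scaled numeric covariates, and
  one-hot dummies for categorical covariates (first level as the
  omitted baseline). `theta > 0` is the dispersion in the size–mu
  parameterization, so `Var(N) = mu + mu²/theta`; small `theta` means
  strong aggregation.
* **Sampling.** With probability `pi_i = logistic(x_i'gamma)` the cell
  is never visited and contributes an *excess zero*; otherwise the
  observed count is `Binomial(N_i, d)` with detection probability `d`
  (default 1 — the bias modelled here is zero-generating, not
  detection-driven; thinning is available as an optional stressor).

The zero-inflated likelihood fitted to the observed per-cell counts is
the exact mixture of these two processes, which is why the generator
and the estimator are twins: parameter recovery on synthetic data is a
meaningful check of the fitting code, and the excess-zero flags the
generator retains (never shown to fitting code) let tests measure how
well the count component recovers true abundance in censored cells.

## Synthetic landscape generator

Numeric covariates are white noise smoothed with a Gaussian kernel of
spatial scale `covariate_correlation_length` (default 5 km on a 1-km
grid) and re-standardized — a cheap surrogate for a Gaussian process
that reproduces the one property the analysis needs, spatial
smoothness. Categorical covariates threshold an independent smoothed
latent field at its quantiles, giving spatially coherent, roughly
equal-area classes like land-class maps. Records are placed uniformly
within their generating cell; recorder home bases are uniform over the
landscape and records are assigned to recorders with probability
`∝ exp(−distance/activity_decay)` (the decay scale is a free modelling
choice — nothing in real inventories pins it down — default 10 km).

Default study conditions (the `DEFAULT_CONFIG` in
`biastree.pipeline`): a 50×50 grid (2,500 cells), three numeric
covariates plus one three-level class,
`beta = (0.4, 0.8, −0.5, 0.3, 0.3, −0.3)`, `theta = 0.5`,
`gamma = (−0.4, 0.8, 0, −0.5, 0.3, 0)`. These were chosen once to give
a landscape that looks like a heavily overdispersed, sparsely occupied
inventory: ~3,000 records concentrated in ~25% of cells, a
variance:mean ratio well above 1, and roughly 40% of cells censored by
the covariate-driven non-sampling process. The zero process shares its
leading covariate with the count process, which is the hard case for
bias separation and the realistic one (accessibility correlates with
habitat).

What the generator does **not** emulate: detection heterogeneity
between recorders, temporal accumulation of records, positional error,
roads/path networks as line features, and multi-species target groups.
Passing tests therefore demonstrate that each correction behaves as
designed under covariate-driven zero-generation — not that any of them
removes every bias present in a real inventory.

## Bias corrections

* `systematic_sample`: one uniformly chosen record per occupied coarse
  cell; the coarse grid is anchored at the landscape origin (the anchor
  affects membership only at boundaries and is configurable).
* `cluster_filter`: single-linkage components of the strictly-less-than
  `link_distance` graph (chains count as one cluster); one record kept
  per component.
* `weighted_distance_sample`: nearest-neighbour distances are min–max
  rescaled to [0, 1] and records drawn sequentially without
  replacement with probability proportional to weight, implemented via
  exponential sort keys (Efraimidis–Spirakis), which reproduces that
  draw exactly; zero-weight records become eligible only after every
  positive-weight record.
* Bias surfaces: Gaussian kernel densities of point sets (the kernel
  family matters less than the surface shape; bandwidth defaults to
  5 cell sizes), min–max rescaled rasters with an explicit
  ascending/descending direction (the right direction for
  distance-type sources is a modelling decision, so it is a parameter,
  never guessed), and the record density itself. Weighted backgrounds
  draw cells with replacement proportional to weight, then place a
  uniform point in the drawn cell; presence cells are not excluded.
* Buffer-restricted backgrounds sample by rejection from the bounding
  box of the buffer union; a try cap guards termination.

## Presence–background model

MaxEnt-style suitability is represented by a penalized logistic
regression of presences (1) against background points (0) on per-point
covariates — the standard infinitely-weighted-points equivalence makes
the two interchangeable for *relative* suitability, and an explicit
GLM keeps every coefficient inspectable. Ridge penalty `lambda` on
non-intercept terms; features are linear (+ optional quadratic
numeric). Model selection minimizes
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)` with `k` the raw count of non-zero
coefficients including the intercept (a hat-trace effective `k` was
considered and rejected as needlessly indirect for the grids used
here); ties break toward smaller `k`. The stored log-likelihood is the
unpenalized one at the penalized optimum. Complete separation at
`lambda = 0` (coefficients diverging past |30|) raises an error
suggesting a positive penalty rather than returning a meaningless fit.

## Zero-inflated fitting

The ZI log-likelihood is computed with log-sum-exp stability
(`log[pi + (1−pi) f(0)]` via `logaddexp`), with analytic gradients for
both components and for `log(theta)` — `theta` is optimized on the log
scale to keep the problem unconstrained, and the fitted table reports
`Log(theta)` accordingly. Warm starts: count coefficients from a plain
Poisson GLM on positive-count cells, zero coefficients from a logistic
GLM on the indicator `y = 0`, `theta` from a method-of-moments
estimate. Optimization is L-BFGS with a full-BFGS polish if the
gradient criterion (`max|g| < 1e-6 · (1 + |ℓ|)`, max 500 iterations)
is not yet met; non-convergence is surfaced in the `converged` flag,
never masked. Standard errors come from the inverse observed
information, with the Hessian taken by central differences of the
analytic score. Both components receive the full covariate design by
default; separate designs can be passed.

Vuong's non-nested comparison uses the per-observation log-likelihood
differences `m_i`, `Z = (Σm_i − C)/(√n · sd(m))`, with `C` zero, the
AIC parameter difference, or the AICc penalty difference. `Z < 0`
favours the second model. When `sd(m) = 0`, `Z = 0` is returned only
if the corrected numerator also vanishes (identical models); otherwise
the statistic is undefined and an error is raised.

A note on family choice: fitting the Poisson count component to
NB-generated data pushes the unmodelled overdispersion into the zero
component, inflating both `pi` and `mu`. This is visible in the test
suite's bias-separation property, which therefore uses the
well-specified NB family — the same family the Vuong comparison
selects on such data.

## Evaluation and calibration

Cross-validation assigns cells to k (default 10) near-equal random
folds — no spatial blocking, since cell-level random folds are the
configuration the workflow targets. AUC is the rank (Mann–Whitney)
statistic with ties counted half. Abundance predictions are binarized
at a mean (internal CV) or median (field comparison) threshold with a
strict `>` at the boundary; the threshold's reference set is explicit,
because field thresholds are computed over all *selected* squares even
when only a subset was completed. RMSLE uses natural logs of `1 + x`.

Field surveys: squares are a random tranche (default 20 on the 2,500-
cell grid; 50 in the classic 90-square design) plus four strata of
(has records?) × (predicted excess-zero probability above/below its
mean), each stratum sampled without replacement and without reuse.
Accessibility is simulated as a small rejection-and-replacement
probability (default 0.044) and incompleteness as a per-square
completion probability (default 0.58); calibration uses completed
squares only. Coverage fractions are Beta(2.2, 1.5) clipped to
[0.05, 1], giving a mean near 0.6 with occasional complete surveys.
Effort-adjusted density is `count/(coverage × cell area)` in trees per
m²; density-metric totals multiply calibrated per-cell density by the
cell area (10⁶ m²), the unit-consistent reading of "summing"
calibrated estimates. Negative calibrated cell estimates are retained
by default (clipping at zero is available and reported separately when
used).

**Known behaviour of the total.** The stratified tranche selects on
the realized records (`Y > 0`), i.e. partly on the outcome, so
calibrations that pool it with the random tranche inherit a
preferential-sampling bias; together with the small number of
completed squares this makes the landscape total heavy-tailed. Across
100 pipeline replicates under the default conditions the
total-to-truth ratio has median ≈ 1.05 with a 95% range of roughly
0.3–2.9 (recomputed, not assumed, by `scripts/acceptance.py`). The
acceptance check on the total is therefore a replicate-interval check,
not a point comparison.

## Problem sizes

All shipped analyses run on one CPU in minutes: the default study grid
is 50×50 cells with ~3,000 records; replicate-based properties use 50
replicates (bias separation, Vuong direction at n = 5,000) and 100
closed-loop replicates for the total-recovery interval. Larger grids
are a config change (`synthetic.n_rows/n_cols`); every stage is
vectorized or uses spatial indexing with average-case linear cost.

## Limitations

* The suitability model deliberately omits hinge/threshold features and
  MaxEnt's regularization schedule; no numerical agreement with MaxEnt
  outputs is attempted.
* No spatial random effects or autocorrelation terms in the ZI model;
  residual spatial structure is checked (correlation of residuals with
  easting/northing) but not modelled.
* Raster I/O is CSV-based (cell tables and surface tables); no
  reprojection or CRS handling — coordinates are assumed projected
  metres throughout.
* Hurdle models, environmental-space filtering and target-group
  backgrounds are out of scope.
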