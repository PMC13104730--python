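# Methods

## Traits

**Somatic growth rate.** Each animal that survives to first reproduction
contributes `g = (ln M_t − ln M_0) / t`, with `M_0` its dry mass at birth,
`M_t` at first reproduction, and `t` the age at first reproduction in
days. Units cancel in the ratio, so `g` is unit-invariant; masses are
recorded in µg by convention. Negative `g` is legitimate (mass loss below
the starvation threshold) and is never truncated before fitting. Because
initial masses are typically weighed on pooled neonate subsamples, `M_0`
may be a clone-level mean applied to every individual; the schema accepts
either, and the generator uses clone-mean initial mass by default.

**Early-life intrinsic rate of increase.** `r` solves the Euler–Lotka
renewal equation `1 = Σ e^(−r x) l_x m_x` over the age schedule truncated
at the first reproductive event. One animal's schedule has a single term:
its own age at first reproduction `x` and clutch size `m_x`, combined with
the *cohort* survival `l_x` of its clone × concentration stratum (fraction
of animals that survived to reproduce; configurable to per-clone pooling).
The solver brackets `r` in [−5, 5] day⁻¹, doubling the bracket to at most
±50 until the sign changes, then runs Brent's method. For a single-event
schedule the root is `ln(l_x m_x) / x` in closed form; the solver is
required (and tested) to agree to ≤ 1e-8 absolute, and the bootstrap uses
the closed form directly for speed. Animals that died contribute to the
`l_x` denominator only; survivors with an empty brood chamber (clutch 0)
also yield no `r` observation — maturity is defined by eggs present, so a
zero-clutch animal has not yet reproduced. Both kinds of skip are logged
and tallied in the run report, never silently dropped.

This is an early-life `r`: it measures population growth potential through
the first clutch and deliberately ignores later reproduction.

## Plateau models

The quadratic-plateau mean function has three free parameters: intercept
`b₀`, initial slope `b₁`, break-point `c_x` (the ILL). The quadratic term
is derived, `b₂ = −b₁/(2c_x)` — the unique choice making the curve join
its plateau with zero slope, which also fixes the plateau elevation at
`b₀ + b₁ c_x / 2` (asserted on every fit, together with the smooth-join
identity `b₁ + 2 b₂ c_x = 0`). The TFL is the smaller root of
`b₀ + b₁ x + b₂ x² = 0` when it lies in `[0, c_x]`; a curve positive at
zero food (`b₀ > 0`) has no estimable TFL, reported as `NA` rather than an
error. The hockey-stick alternative `y = b₀ + b₁ min(x, c_x)` keeps the
same interface with plateau `b₀ + b₁ c_x` and TFL `−b₀/b₁`.

**Fitting.** Unweighted least squares over individual observations (a
stratum-means mode exists as a configuration switch; individual points are
the default because the scatter, not the cell means, carries the
within-stratum sampling variance the bootstrap resamples). Both models are
partially linear — at fixed `c_x` they are OLS in `(b₀, b₁)` — which is
exploited three ways:

1. *Self-start*: plateau guess = mean response over the two highest
   concentration levels; slope/intercept from an OLS line through points
   below the median concentration; break-point guess where that line meets
   the plateau guess, clamped into (smallest positive x, max x]. Flat or
   declining data raise a degenerate-data warning.
2. *Primary optimizer*: trust-region-reflective damped least squares
   (analytic Jacobian, `c_x` bounded in (0, max x], tolerances 1e-12).
   After it returns, a nearly free profiled-RSS scan over a 20-point
   log-spaced `c_x` grid (closed-form OLS per point) checks for a better
   optimum; landing above the scan counts as failure. On failure the
   *fallback* reruns damped least squares from every grid point and keeps
   the lowest RSS, ties broken toward the smaller break-point (parsimony
   toward earlier saturation). Results record which path succeeded.
3. *Oracle*: `profile_grid_oracle` solves the OLS profile on a dense
   (default 1000-point) grid — an independent brute-force minimizer used
   in tests to bound the optimizer's RSS.

Break-point estimates within 1e-6 (relative) of the largest observed
concentration are flagged `at_boundary` rather than rejected: a curve
still rising at the top of the design has no identified plateau, and the
flag, not an error, lets wide bootstrap intervals express that.

## Bootstrap inference

Nonparametric, 1000 iterations and 95% equal-tailed percentile intervals
by default (percentile rather than BCa/basic: the minimal choice matching
bracket-style interval reporting; quantiles use the linear-interpolation
(type-7) convention, fixed for bit-reproducibility). Two schemes:

- **Growth (stratified)**: growth observations are resampled with
  replacement within every concentration stratum, preserving stratum
  sizes, and the model is refit. Since concentrations are identical within
  a stratum, only the responses need regathering.
- **r (individual)**: whole individuals — age, clutch and survival jointly,
  including non-survivors — are resampled within strata; stratum `l_x` and
  every `r` are recomputed from the resample before refitting. Recomputing
  `l_x` per resample is the default (`lx_mode="varying"`) because holding
  it fixed would understate variance; the fixed mode exists for
  sensitivity checks.

Refits start from the point estimate (warm start). Failed refits are
recorded as missing and counted — never imputed; a warning is issued above
5% failures and inference aborts above 50%. The plateau-elevation interval
is taken from the distribution of each resample's *own* predicted response
at its *own* break-point, so parameter covariance propagates.

**Clone comparison.** Clones are ordered by interval overlap: `A < B` only
when A's upper bound is below B's lower bound, `=` otherwise, sorted by
lower bound and rendered as e.g. `B3 = B2 < D2 = D4`. The relation is not
transitive and no closure is taken; `strictly_less` exposes pairwise
verdicts directly.

## Synthetic data

The generator emulates the reference experiment: 12 nominal concentrations
(0.0125, 0.025, 0.05, 0.1, 0.15, 0.25, 0.35, 0.5, 1.0, 1.5, 2.5, 4.5
mg C_org L⁻¹) × 10 replicates per clone, one animal per vessel, inspected
daily. Per animal: survival ~ Bernoulli(0.95 by default); true growth rate
= the clone's quadratic-plateau curve truncated below at zero, plus
additive Gaussian noise on the rate scale (default sd 0.03 day⁻¹ — the
response-scale scatter of such experiments is not published, so this is a
convention chosen to make recovery tests informative at n = 120 per
clone, not a measured value; noise on the rate rather than the mass scale
matches how the scatter presents in growth-rate plots); age at first
reproduction interpolates from 14 d near zero food to 8–9 d above the
break-point, rounded up to whole days (daily inspections); clutch size is
negative-binomial with saturating mean `clutch_max · c / (c + 0.15)` and
size parameter 15; final mass is back-computed as `M₀ e^{g·AFR}` so the
analysis recovers the simulated rate exactly. Non-survivors carry no final
mass, age or clutch.

Default clone parameters place true growth ILLs at 0.651–1.05 mg C_org L⁻¹
and plateaus at 0.381–0.496 day⁻¹, i.e. in the regime reported for
*D. magna* clones from pond and lake habitats, so simulation studies run
at realistic signal-to-noise. Default intercepts are −0.008 day⁻¹, putting
the true TFL near 0.01 mg C_org L⁻¹ — below the lowest design
concentration, so the zero-truncation of the true curve never touches the
tested range and noiseless recovery is exact. The r-trait curve is
*emergent* (from the AFR, clutch and survival schedules), not directly
parameterized; its ILL has no closed-form truth, which is why recovery
tests target the growth trait.

What the generator does **not** emulate: within-vessel algal depletion
between daily medium exchanges (concentrations are treated as nominal
initial values, as in the source experimental design), body-size
allometry, multiple clutches, diapause, or food-dependent mortality.
Passing recovery tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to those real-data
features.

## Numerical and reproducibility choices

- All randomness flows from integer seeds through `numpy`'s `SeedSequence`;
  the pipeline spawns one child stream per clone × trait × model in fixed
  order, so adding a clone does not perturb another clone's resamples.
- Output CSVs are written with `%.10g` floats and `NA` for missing; run
  reports carry the config echo and no timestamps, so identical
  configurations produce byte-identical files.
- Simulation-based checks in the test suite use 500 replicates for
  estimator calibration (median ILL error, CI coverage with 300 resamples)
  and 200 replicates for discrimination power — sizes chosen to keep
  binomial noise on the measured rates small while the whole suite stays
  desk-scale.

## Known limitations

- Percentile intervals for a break-point are first-order correct but can
  under-cover slightly at small n; measured coverage at the reference
  design is ~0.92–0.93 against the nominal 0.95.
- The hockey-stick fit applied to smoothly saturating data systematically
  places its abrupt threshold below the quadratic-plateau ILL; the two
  models answer "where does saturation begin" under different shape
  assumptions and are reported side by side, never model-averaged.
- With `c_x` at the design boundary the plateau elevation is extrapolation;
  the `at_boundary` flag should gate any downstream interpretation.
- The early-life `r` ignores reproduction after the first clutch by
  construction; it is a comparative index across clones and food levels,
  not a full life-table intrinsic rate.
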