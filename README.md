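# illfit

Saturation-curve analysis of zooplankton life-history traits along a food
gradient: clone-specific **incipient limiting levels** (ILL), **plateau
elevations** and **threshold food levels** (TFL), with nonparametric
bootstrap confidence intervals.

## The problem

Planktonic grazers such as *Daphnia* respond to food (algal carbon)
concentration nonlinearly: a fitness trait — somatic growth rate, egg
production, population growth rate — rises with food and then saturates.
Three quantities summarize the response curve of a clonal lineage:

- **ILL** — the food concentration above which the trait no longer
  increases (the break-point of the saturation curve). Laboratory studies
  conventionally treat ~1 mg C_org L⁻¹ as *ad libitum* for all genotypes;
  clone-specific ILL estimates test that assumption.
- **Plateau elevation** — the trait value attained at and above the ILL:
  maximal performance under non-limiting food.
- **TFL** — the food concentration at which the trait crosses zero
  (the x-intercept of the fitted curve): the starvation threshold.

`illfit` estimates all three per clone from per-individual records of a
food-gradient experiment, for two traits:

- **somatic growth rate** `g = (ln M_t − ln M_0) / t` (day⁻¹), from dry
  masses at birth and at first reproduction;
- **early-life intrinsic rate of increase** `r` (day⁻¹), solving the
  Euler–Lotka equation `1 = Σ e^(−r x) l_x m_x` with the age schedule
  truncated at the first reproductive event (age at first reproduction
  `x`, first clutch size `m_x`, cohort survival `l_x`).

## The model

The primary mean function is the three-parameter **quadratic plateau**:

    y(x) = b₀ + b₁ x + b₂ x²   for x ≤ c_x,      b₂ = −b₁ / (2 c_x)
    y(x) = b₀ + b₁ c_x / 2     for x > c_x

The quadratic coefficient is derived, not free: it is the unique value
giving a smooth (zero-slope) join at the break-point `c_x` = ILL. The
plateau elevation is the predicted response at the ILL, `b₀ + b₁ c_x / 2`;
the TFL is the smaller root of the rising branch (not estimable when
`b₀ > 0`). A piecewise-linear **hockey-stick** model
`y = b₀ + b₁ · min(x, c_x)` is available as a structural robustness check.

Fits are unweighted nonlinear least squares over individual observations
(trust-region damped least squares with an analytic Jacobian, deterministic
self-starting values, and a multi-start fallback grid on `c_x`).
Uncertainty comes from a nonparametric bootstrap (1000 iterations, 95%
percentile intervals by default): growth observations are resampled within
each clone × concentration stratum; for `r`, whole individuals (age,
clutch, survival) are resampled and `l_x` and every `r` are recomputed per
resample. Clones are compared by CI overlap: `A < B` only when A's upper
bound lies below B's lower bound, rendered in the conventional notation,
e.g. `B3 = B2 < D2 = D4`.

A synthetic-data generator (`illfit.simulate`) produces per-individual
datasets with known ground truth under the reference design — 4 clones ×
12 concentrations (0.0125–4.5 mg C_org L⁻¹) × 10 replicates = 480
animals — so the whole pipeline is testable end to end.

## Worked example

```python
from illfit import (CloneSpec, ExperimentDesign, BootstrapConfig,
                    generate_dataset, growth_observations,
                    fit_quadratic_plateau, bootstrap_growth_fit)

truth = CloneSpec("demo", g_intercept=-0.008, g_slope=1.16,
                  g_breakpoint=0.7, survival_prob=1.0, g_noise_sd=0.03)
records = generate_dataset(ExperimentDesign(seed=7), [truth])
obs = growth_observations(records)
fit = fit_quadratic_plateau(obs["concentration_mgC_per_L"].to_numpy(),
                            obs["g"].to_numpy())
print(f"{fit.ill:.4f} {fit.plateau_elevation:.4f} {fit.tfl:.4f}")
boot = bootstrap_growth_fit(records, BootstrapConfig(n_resamples=1000, seed=1))
print(boot["ill"][1])
```

This prints:

```
0.7433 0.4008 0.0065
ConfidenceInterval(lower=0.6940528858182419, upper=0.792348097025988, level=0.95, method_tag='percentile')
```

i.e. from 120 simulated animals the estimated ILL is 0.74 mg C_org L⁻¹
and its bootstrap 95% CI [0.69, 0.79] covers the generating truth of
0.70; the clone's maximal growth rate is 0.401 day⁻¹ (truth 0.398), and
growth crosses zero near 0.0065 mg C_org L⁻¹. The scripts in
`examples/` walk through simulation, fitting, bootstrapping and the full
four-clone pipeline (`python examples/04_full_pipeline.py`), which ends
with CI-overlap orderings such as `g: B3 < B2 < D4 = D2`.

Real datasets enter through `read_records_csv` (columns `clone_id,
concentration_mgC_per_L, initial_mass_ug, final_mass_ug,
age_first_repro_d, clutch_size, survived`), or via the thin CLI:

```sh
illfit simulate --out records.csv --seed 3
illfit run --input records.csv --out-dir out --resamples 1000 --seed 3
```

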