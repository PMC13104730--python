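"""Stratified bootstrap CIs and CI-overlap clone ordering."""

import numpy as np
import pytest

from illfit import (BootstrapConfig, CloneSpec, ConfidenceInterval,
                    ExperimentDesign, InvalidInputError, bootstrap_growth_fit,
                    bootstrap_r_fit, compare_by_ci, fit_quadratic_plateau,
                    generate_dataset, growth_observations, percentile_ci,
                    with_zero_noise)

from conftest import make_records, survivor


class TestPercentileCI:
    def test_constant_samples_zero_width(self):
        ci = percentile_ci([0.7] * 50)
        assert (ci.lower, ci.upper) == (0.7, 0.7)

    def test_linear_interpolation_convention(self):
        # hand value for the 2.5%/97.5% type-7 quantiles of 1..1000
        ci = percentile_ci(np.arange(1, 1001), level=0.95)
        assert ci.lower == pytest.approx(25.975)
        assert ci.upper == pytest.approx(975.025)

    def test_nan_samples_dropped(self):
        ci = percentile_ci([1.0, np.nan, 2.0, np.nan, 3.0], level=0.5)
        assert ci.lower == pytest.approx(1.5)
        assert ci.upper == pytest.approx(2.5)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.1])
    def test_degenerate_level_rejected(self, level):
        with pytest.raises(InvalidInputError):
            percentile_ci([1, 2, 3], level=level)

    def test_all_missing_rejected(self):
        with pytest.raises(InvalidInputError):
            percentile_ci([np.nan, np.nan])


@pytest.fixture(scope="module")
def noisy_records():
    spec = CloneSpec("A", g_slope=1.16, g_breakpoint=0.7, survival_prob=1.0,
                     g_noise_sd=0.03)
    return generate_dataset(ExperimentDesign(seed=21), [spec])


class TestGrowthBootstrap:
    def test_seeded_determinism(self, noisy_records):
        cfg = BootstrapConfig(n_resamples=50, seed=5)
        a = bootstrap_growth_fit(noisy_records, cfg)
        b = bootstrap_growth_fit(noisy_records, cfg)
        assert a["ill"][1] == b["ill"][1]
        np.testing.assert_array_equal(a["ill"][0].samples, b["ill"][0].samples)
        c = bootstrap_growth_fit(noisy_records, BootstrapConfig(n_resamples=50,
                                                                seed=6))
        assert a["ill"][1] != c["ill"][1]

    def test_noiseless_data_zero_width_intervals(self):
        spec = with_zero_noise(CloneSpec("A", g_slope=1.16, g_breakpoint=0.7))
        recs = generate_dataset(ExperimentDesign(seed=2), [spec])
        out = bootstrap_growth_fit(recs, BootstrapConfig(n_resamples=30, seed=1))
        for tag in ("ill", "plateau"):
            ci = out[tag][1]
            assert ci.upper - ci.lower <= 1e-9

    def test_single_resample_reproduces_point_fit_scale(self, noisy_records):
        # with one resample the distribution is a single refit statistic,
        # close to (and for noiseless data equal to) the point estimate
        obs = growth_observations(noisy_records)
        point = fit_quadratic_plateau(obs["concentration_mgC_per_L"].to_numpy(),
                                      obs["g"].to_numpy())
        out = bootstrap_growth_fit(noisy_records,
                                   BootstrapConfig(n_resamples=1, seed=3))
        assert out["ill"][0].samples.size == 1
        assert abs(out["ill"][0].samples[0] - point.ill) < 0.5
        assert out["ill"][1] is None  # CI needs >= 2 samples

    def test_point_estimate_inside_ci(self, noisy_records):
        obs = growth_observations(noisy_records)
        point = fit_quadratic_plateau(obs["concentration_mgC_per_L"].to_numpy(),
                                      obs["g"].to_numpy())
        out = bootstrap_growth_fit(noisy_records,
                                   BootstrapConfig(n_resamples=200, seed=9))
        assert out["ill"][1].contains(point.ill)
        assert out["plateau"][1].contains(point.plateau_elevation)

    def test_wrong_scheme_rejected(self, noisy_records):
        with pytest.raises(InvalidInputError):
            bootstrap_growth_fit(noisy_records,
                                 BootstrapConfig(scheme="r_individual"))

    def test_multi_clone_input_rejected(self, four_clone_specs):
        recs = generate_dataset(ExperimentDesign(seed=1), four_clone_specs)
        with pytest.raises(InvalidInputError):
            bootstrap_growth_fit(recs, BootstrapConfig(n_resamples=5))

    def test_halving_stratum_n_does_not_shrink_intervals(self):
        # median CI width with 5 animals per cell >= width with 10 per cell
        spec = CloneSpec("A", g_slope=1.16, g_breakpoint=0.7,
                         survival_prob=1.0, g_noise_sd=0.03)
        widths = {}
        for reps in (10, 5):
            w = []
            for sim in range(8):
                d = ExperimentDesign(replicates_per_cell=reps, seed=100 + sim)
                recs = generate_dataset(d, [spec])
                out = bootstrap_growth_fit(
                    recs, BootstrapConfig(n_resamples=150, seed=sim))
                ci = out["ill"][1]
                w.append(ci.upper - ci.lower)
            widths[reps] = float(np.median(w))
        assert widths[5] >= widths[10]


class TestRBootstrap:
    def test_identical_individuals_zero_width(self):
        rows = []
        for conc in (0.05, 0.15, 0.5, 1.0, 2.5, 4.5):
            m = 4 + 10 * conc / (conc + 0.2)
            rows += [survivor(conc=conc, age=9, clutch=round(m))
                     for _ in range(8)]
        recs = make_records(rows)
        out = bootstrap_r_fit(recs, BootstrapConfig(n_resamples=30, seed=4,
                                                    scheme="r_individual"))
        ci = out["ill"][1]
        assert ci.upper - ci.lower <= 1e-9

    def test_varying_lx_widens_or_matches_fixed_lx(self, four_clone_specs):
        spec = CloneSpec("A", g_slope=1.0, g_breakpoint=0.8,
                         survival_prob=0.85, g_noise_sd=0.03)
        recs = generate_dataset(ExperimentDesign(seed=31), [spec])
        out_v = bootstrap_r_fit(recs, BootstrapConfig(
            n_resamples=150, seed=2, scheme="r_individual", lx_mode="varying"))
        out_f = bootstrap_r_fit(recs, BootstrapConfig(
            n_resamples=150, seed=2, scheme="r_individual", lx_mode="fixed"))
        width = lambda o, t: o[t][1].upper - o[t][1].lower
        # survival variability must not make the plateau CI narrower
        assert width(out_v, "plateau") >= 0.8 * width(out_f, "plateau")

    def test_seeded_determinism(self, single_clone_spec):
        recs = generate_dataset(ExperimentDesign(seed=8), [single_clone_spec])
        cfg = BootstrapConfig(n_resamples=40, seed=12, scheme="r_individual")
        a = bootstrap_r_fit(recs, cfg)
        b = bootstrap_r_fit(recs, cfg)
        assert a["ill"][1] == b["ill"][1]


class TestCompareByCI:
    def test_disjoint_intervals_strictly_ordered(self):
        # reported pond-vs-lake growth ILL intervals: disjoint
        cis = {"B2": ConfidenceInterval(0.694, 0.783),
               "D2": ConfidenceInterval(0.97, 1.12)}
        o = compare_by_ci(cis)
        assert str(o) == "B2 < D2"
        assert o.strictly_less("B2", "D2")

    def test_identical_intervals_tied(self):
        cis = {"A": ConfidenceInterval(0.5, 0.7),
               "B": ConfidenceInterval(0.5, 0.7)}
        assert str(compare_by_ci(cis)) in ("A = B", "B = A")

    def test_chained_overlap_reported_without_closure(self):
        cis = {"A": ConfidenceInterval(0.0, 1.0),
               "B": ConfidenceInterval(0.9, 2.0),
               "C": ConfidenceInterval(1.9, 3.0)}
        o = compare_by_ci(cis)
        assert str(o) == "A = B = C"  # A and C disjoint, but no closure taken
        assert o.strictly_less("A", "C")

    def test_four_group_rendering(self):
        cis = {"B3": ConfidenceInterval(0.574, 0.723),
               "B2": ConfidenceInterval(0.694, 0.783),
               "D2": ConfidenceInterval(0.97, 1.12),
               "D4": ConfidenceInterval(0.94, 1.19)}
        assert str(compare_by_ci(cis)) == "B3 = B2 < D4 = D2"

    def test_single_clone_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_by_ci({"A": ConfidenceInterval(0, 1)})
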