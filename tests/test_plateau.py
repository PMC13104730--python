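"""Quadratic-plateau / hockey-stick fitting, TFL derivation, grid oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from illfit import (HockeyStickParams, InsufficientDesignError,
                    QuadraticPlateauParams, REFERENCE_CONCENTRATIONS,
                    derive_tfl, fit_hockey_stick, fit_quadratic_plateau,
                    hockeystick_predict, profile_grid_oracle,
                    quadplateau_predict, selfstart_quadplateau)
from illfit.plateau import HOCKEY_STICK, DegenerateDataWarning

CONCS = np.array(REFERENCE_CONCENTRATIONS)


def quad_data(b0=0.0, b1=0.8, cx=1.0, reps=1, noise=0.0, seed=0):
    p = QuadraticPlateauParams(b0, b1, cx)
    x = np.repeat(CONCS, reps)
    y = quadplateau_predict(p, x)
    if noise:
        y = y + np.random.default_rng(seed).normal(0, noise, x.size)
    return x, np.asarray(y, float), p


class TestPredict:
    def test_rising_branch_hand_value(self):
        p = QuadraticPlateauParams(0.0, 0.8, 1.0)
        assert quadplateau_predict(p, 0.5) == pytest.approx(0.3)

    def test_plateau_value_and_intercept(self):
        p = QuadraticPlateauParams(0.0, 0.8, 1.0)
        assert quadplateau_predict(p, 2.0) == pytest.approx(0.4)  # b0 + b1*cx/2
        assert quadplateau_predict(p, 0.0) == p.b0

    def test_smooth_join(self):
        p = QuadraticPlateauParams(0.1, 0.8, 1.3)
        eps = 1e-7
        left = quadplateau_predict(p, p.cx - eps)
        right = quadplateau_predict(p, p.cx + eps)
        assert left == pytest.approx(right, abs=1e-10)
        # derivative zero at the join: b1 + 2 b2 cx == 0 exactly
        assert p.b1 + 2 * p.b2 * p.cx == 0.0

    def test_hockey_stick_piecewise(self):
        p = HockeyStickParams(-0.1, 0.5, 1.0)
        assert hockeystick_predict(p, 0.5) == pytest.approx(0.15)
        assert hockeystick_predict(p, 3.0) == pytest.approx(0.4)


class TestSelfStart:
    def test_brackets_truth_on_reference_design(self):
        x, y, _ = quad_data()
        s = selfstart_quadplateau(x, y)
        assert 0.5 <= s.cx <= 2.0
        assert s.b1 > 0

    def test_flat_data_flagged_degenerate(self):
        x = CONCS
        y = np.full_like(x, 0.4)
        with pytest.warns(DegenerateDataWarning):
            s = selfstart_quadplateau(x, y)
        assert s.b1 == 0.0

    def test_monotone_data_clamps_to_max_x(self):
        # accelerating data: the low-food line reaches the plateau guess
        # only beyond the design, so the break-point guess clamps to max x
        x = CONCS
        y = 0.02 * x ** 2
        s = selfstart_quadplateau(x, y)
        assert s.cx == pytest.approx(x.max())

    def test_too_few_levels_rejected(self):
        with pytest.raises(InsufficientDesignError):
            selfstart_quadplateau([0.1, 0.5, 1.0] * 3, [0.1, 0.2, 0.3] * 3)


class TestQuadraticPlateauFit:
    def test_noiseless_recovery_to_machine_precision(self):
        x, y, truth = quad_data(b0=0.0, b1=0.8, cx=1.0)
        fit = fit_quadratic_plateau(x, y)
        assert fit.params.b0 == pytest.approx(truth.b0, abs=1e-8)
        assert fit.params.b1 == pytest.approx(truth.b1, rel=1e-6)
        assert fit.ill == pytest.approx(truth.cx, rel=1e-6)
        assert fit.plateau_elevation == pytest.approx(truth.plateau, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.converged

    def test_fitted_rss_dominates_truth_rss(self):
        x, y, truth = quad_data(reps=10, noise=0.03, seed=42)
        fit = fit_quadratic_plateau(x, y)
        rss_truth = float(np.sum((y - quadplateau_predict(truth, x)) ** 2))
        assert fit.rss <= rss_truth + 1e-12

    def test_breakpoint_beyond_design_hits_boundary(self):
        # truth saturates far above the largest tested concentration
        x, y, _ = quad_data(b0=0.0, b1=0.2, cx=10.0)
        fit = fit_quadratic_plateau(x, y)
        assert fit.at_boundary
        assert fit.ill == pytest.approx(x.max(), rel=1e-6)

    def test_plateau_identity_and_smooth_join_on_fits(self):
        x, y, _ = quad_data(reps=5, noise=0.02, seed=3)
        fit = fit_quadratic_plateau(x, y)
        p = fit.params
        assert fit.plateau_elevation == pytest.approx(p.b0 + p.b1 * p.cx / 2,
                                                      rel=1e-12)
        assert p.b1 + 2 * p.b2 * p.cx == pytest.approx(0.0, abs=1e-12)

    def test_scale_equivariance(self):
        x, y, _ = quad_data(reps=5, noise=0.02, seed=11)
        f1 = fit_quadratic_plateau(x, y)
        f2 = fit_quadratic_plateau(x, 3.0 * y)
        assert f2.params.b0 == pytest.approx(3 * f1.params.b0, abs=1e-6)
        assert f2.params.b1 == pytest.approx(3 * f1.params.b1, rel=1e-4)
        assert f2.ill == pytest.approx(f1.ill, rel=1e-4)
        assert f2.plateau_elevation == pytest.approx(3 * f1.plateau_elevation,
                                                     rel=1e-4)
        if f1.tfl is not None:
            assert f2.tfl == pytest.approx(f1.tfl, rel=1e-3, abs=1e-8)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDesignError):
            fit_quadratic_plateau([0.1, 0.5, 1.0, 2.0], [0.1, 0.2, 0.3, 0.3])


class TestHockeyStickFit:
    def test_noiseless_recovery(self):
        truth = HockeyStickParams(-0.1, 0.5, 1.0)
        x = np.repeat(CONCS, 2)
        y = hockeystick_predict(truth, x)
        fit = fit_hockey_stick(x, y)
        assert fit.params.b0 == pytest.approx(truth.b0, rel=1e-6)
        assert fit.params.b1 == pytest.approx(truth.b1, rel=1e-6)
        assert fit.ill == pytest.approx(truth.cx, rel=1e-6)
        assert fit.plateau_elevation == pytest.approx(0.4, rel=1e-6)
        assert fit.tfl == pytest.approx(0.2, rel=1e-6)

    def test_zero_intercept_tfl_boundary_case(self):
        truth = HockeyStickParams(0.0, 0.5, 1.0)
        x = np.repeat(CONCS, 2)
        fit = fit_hockey_stick(x, hockeystick_predict(truth, x))
        assert fit.tfl == pytest.approx(0.0, abs=1e-8)


class TestDeriveTfl:
    def test_quadratic_root_hand_value(self):
        # b2 = -0.4; roots 1 +/- sqrt(3)/2; rising-branch root ~0.13397
        tfl = derive_tfl(QuadraticPlateauParams(-0.1, 0.8, 1.0))
        assert tfl == pytest.approx(1 - math.sqrt(3) / 2, rel=1e-12)

    def test_zero_intercept_gives_zero(self):
        assert derive_tfl(QuadraticPlateauParams(0.0, 0.8, 1.0)) == 0.0

    def test_positive_at_origin_not_estimable(self):
        assert derive_tfl(QuadraticPlateauParams(0.05, 0.8, 1.0)) is None

    def test_prediction_at_tfl_is_zero(self):
        p = QuadraticPlateauParams(-0.1, 0.8, 1.0)
        assert quadplateau_predict(p, derive_tfl(p)) == pytest.approx(0.0, abs=1e-12)

    def test_hockey_stick_x_intercept(self):
        assert derive_tfl(HockeyStickParams(-0.1, 0.5, 1.0)) == pytest.approx(0.2)
        assert derive_tfl(HockeyStickParams(0.05, 0.5, 1.0)) is None


class TestProfileGridOracle:
    def test_single_truth_gridpoint_exact_recovery(self):
        x, y, truth = quad_data()
        fit = profile_grid_oracle(x, y, cx_grid=[truth.cx])
        assert fit.params.b0 == pytest.approx(truth.b0, abs=1e-10)
        assert fit.params.b1 == pytest.approx(truth.b1, rel=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-14)

    def test_noiseless_truth_recovered_at_nearest_gridpoint(self):
        x, y, truth = quad_data()
        grid = np.linspace(0.0125, 4.5, 1000)
        fit = profile_grid_oracle(x, y, cx_grid=grid)
        step = grid[1] - grid[0]
        assert abs(fit.ill - truth.cx) <= step

    @pytest.mark.parametrize("seed", range(10))
    def test_oracle_never_beats_optimizer_materially(self, seed):
        rng = np.random.default_rng(seed)
        b0 = rng.uniform(-0.1, 0.05)
        b1 = rng.uniform(0.4, 1.5)
        cx = rng.uniform(0.3, 2.0)
        x, y, _ = quad_data(b0=b0, b1=b1, cx=cx, reps=5, noise=0.03, seed=seed + 100)
        opt = fit_quadratic_plateau(x, y)
        oracle = profile_grid_oracle(x, y, cx_grid=np.linspace(0.0125, 4.5, 1000))
        assert opt.rss <= oracle.rss + 1e-9
        assert abs(opt.rss - oracle.rss) / oracle.rss <= 1e-3

    def test_oracle_supports_hockey_stick(self):
        truth = HockeyStickParams(-0.05, 0.5, 1.0)
        x = np.repeat(CONCS, 2)
        y = hockeystick_predict(truth, x)
        fit = profile_grid_oracle(x, y, cx_grid=np.linspace(0.05, 4.5, 2000),
                                  model_tag=HOCKEY_STICK)
        assert abs(fit.ill - truth.cx) <= 4.5 / 2000 * 2


@given(k=st.floats(0.2, 5.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_scaling_response_leaves_breakpoint_invariant(k):
    x, y, _ = quad_data(b0=-0.05, b1=0.9, cx=0.8, reps=3, noise=0.02, seed=5)
    f1 = fit_quadratic_plateau(x, y)
    f2 = fit_quadratic_plateau(x, k * y)
    assert f2.ill == pytest.approx(f1.ill, rel=1e-3)
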