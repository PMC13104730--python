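"""Nonparametric bootstrap confidence intervals for plateau-model estimates.

Two resampling schemes mirror how each trait is observed:

* ``growth_stratified`` — somatic growth rates are direct per-individual
  observations, so each iteration resamples the growth observations with
  replacement *within every clone x concentration stratum*, preserving
  per-stratum sample sizes, then refits the plateau model.

* ``r_individual`` — r is derived from (age at first reproduction, clutch
  size, survival), so each iteration resamples whole individuals within
  strata, recomputes stratum survival l_x from the resample (so survival
  uncertainty propagates), recomputes every r, and refits.

Intervals are percentile intervals from the bootstrap distribution; failed
refits are dropped and counted, never imputed. Clones are ordered by CI
overlap: clone A is strictly below clone B only when A's upper bound lies
below B's lower bound, otherwise the pair is reported as indistinguishable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InferenceFailureError, InvalidInputError
from .life_history import (_euler_lotka_closed_form, compute_r_observations,
                           growth_observations)
from .plateau import (HOCKEY_STICK, QUADRATIC_PLATEAU, PlateauFitResult,
                      fit_hockey_stick, fit_quadratic_plateau)
from .records import check_records

__all__ = [
    "BootstrapConfig",
    "BootstrapDistribution",
    "ConfidenceInterval",
    "bootstrap_growth_fit",
    "bootstrap_r_fit",
    "percentile_ci",
    "compare_by_ci",
    "CloneOrdering",
]

logger = logging.getLogger(__name__)

STATISTIC_TAGS = ("ill", "plateau", "tfl", "b0", "b1")


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings: 1000 iterations and 95% intervals by default."""

    n_resamples: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    scheme: str = "growth_stratified"
    lx_mode: str = "varying"  # recompute l_x per resample; "fixed" holds it

    def __post_init__(self):
        if self.n_resamples < 1:
            raise InvalidInputError("n_resamples must be >= 1")
        if not (0 < self.ci_level < 1):
            raise InvalidInputError("ci_level must be in (0, 1)")
        if self.scheme not in ("growth_stratified", "r_individual"):
            raise InvalidInputError(f"unknown scheme {self.scheme!r}")
        if self.lx_mode not in ("varying", "fixed"):
            raise InvalidInputError(f"unknown lx_mode {self.lx_mode!r}")


@dataclass
class BootstrapDistribution:
    """Resampled values of one statistic; failed refits are NaN."""

    statistic_tag: str
    samples: np.ndarray
    n_failed: int


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95
    method_tag: str = "percentile"

    def __post_init__(self):
        if self.lower > self.upper:
            raise InvalidInputError("CI lower bound exceeds upper bound")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def percentile_ci(samples, level: float = 0.95) -> ConfidenceInterval:
    """Equal-tailed percentile interval with linear-interpolation quantiles.

    Quantiles follow numpy's default ``linear`` convention (Hyndman-Fan
    type 7), fixed here for bit-reproducibility; NaN entries (failed
    refits, not-estimable statistics) are dropped first.
    """
    if not (0 < level < 1):
        raise InvalidInputError("level must be in (0, 1)")
    s = np.asarray(samples, dtype=float)
    s = s[np.isfinite(s)]
    if s.size < 2:
        raise InvalidInputError(
            "need >= 2 non-missing bootstrap samples for a percentile CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(s, [alpha, 1.0 - alpha], method="linear")
    return ConfidenceInterval(float(lo), float(hi), level=level)


_FITTERS = {QUADRATIC_PLATEAU: fit_quadratic_plateau,
            HOCKEY_STICK: fit_hockey_stick}


def _stat_values(fit: PlateauFitResult) -> dict[str, float]:
    return {
        "ill": fit.ill,
        "plateau": fit.plateau_elevation,
        "tfl": np.nan if fit.tfl is None else fit.tfl,
        "b0": fit.params.b0,
        "b1": fit.params.b1,
    }


def _stratum_indices(conc: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(conc == c) for c in np.unique(conc)]


def _collect(samples: dict[str, list], n_failed: int, n_resamples: int,
             level: float):
    if n_failed > 0.5 * n_resamples:
        raise InferenceFailureError(
            f"{n_failed}/{n_resamples} bootstrap refits failed")
    if n_failed > 0.05 * n_resamples:
        warnings.warn(
            f"{n_failed}/{n_resamples} bootstrap refits failed; "
            "intervals may be unstable", stacklevel=3)
    out = {}
    for tag in STATISTIC_TAGS:
        arr = np.asarray(samples[tag], dtype=float)
        dist = BootstrapDistribution(tag, arr, n_failed=n_failed)
        finite = arr[np.isfinite(arr)]
        ci = percentile_ci(arr, level) if finite.size >= 2 else None
        out[tag] = (dist, ci)
    return out


def _bootstrap_fit_loop(x, y_draw, point_fit, model_tag, config):
    """Shared refit loop: ``y_draw(i, rng)`` yields the i-th resampled (x, y)."""
    fitter = _FITTERS[model_tag]
    rng = np.random.default_rng(config.seed)
    samples = {tag: [] for tag in STATISTIC_TAGS}
    n_failed = 0
    for i in range(config.n_resamples):
        xb, yb = y_draw(i, rng)
        try:
            fit = fitter(xb, yb, start=point_fit.params)
            if not fit.converged:
                raise RuntimeError("refit did not converge")
        except Exception:
            n_failed += 1
            for tag in STATISTIC_TAGS:
                samples[tag].append(np.nan)
            continue
        for tag, val in _stat_values(fit).items():
            samples[tag].append(val)
    return _collect(samples, n_failed, config.n_resamples, config.ci_level)


def bootstrap_growth_fit(records: pd.DataFrame, config: BootstrapConfig,
                         model_tag: str = QUADRATIC_PLATEAU,
                         point_fit: PlateauFitResult | None = None):
    """Bootstrap CIs for the growth-rate plateau fit of one clone.

    Resamples growth observations with replacement within each
    concentration stratum (stratum sizes preserved), refits, and collects
    the break-point (ILL), plateau elevation, TFL and the raw coefficients.
    Returns a dict mapping statistic tag to (BootstrapDistribution,
    ConfidenceInterval); deterministic given ``config.seed``.
    """
    if config.scheme != "growth_stratified":
        raise InvalidInputError("config.scheme must be 'growth_stratified'")
    records = check_records(records)
    _require_single_clone(records)
    obs = growth_observations(records)
    x = obs["concentration_mgC_per_L"].to_numpy()
    y = obs["g"].to_numpy()
    if point_fit is None:
        point_fit = _FITTERS[model_tag](x, y)
    strata = _stratum_indices(x)

    def draw(_i, rng):
        idx = np.concatenate([s[rng.integers(0, s.size, s.size)] for s in strata])
        # x is constant within each stratum, so only y needs gathering
        return x, y[idx]

    return _bootstrap_fit_loop(x, draw, point_fit, model_tag, config)


def bootstrap_r_fit(records: pd.DataFrame, config: BootstrapConfig,
                    model_tag: str = QUADRATIC_PLATEAU,
                    point_fit: PlateauFitResult | None = None,
                    lx_scope: str = "stratum"):
    """Bootstrap CIs for the intrinsic-rate-of-increase plateau fit.

    Resamples whole individuals (their age, clutch and survival jointly)
    with replacement within each stratum, recomputes stratum survival and
    every r from the resample, and refits. With ``config.lx_mode ==
    "fixed"`` the original stratum l_x is reused, so only fecundity and
    age variability propagate.

    r is recomputed with the closed form ln(l_x m_x)/x, exact for the
    single-event schedule and identical (to solver tolerance) to the
    numerical Euler-Lotka solution used for point estimates.
    """
    if config.scheme != "r_individual":
        raise InvalidInputError("config.scheme must be 'r_individual'")
    records = check_records(records)
    _require_single_clone(records)

    conc_all = records["concentration_mgC_per_L"].to_numpy()
    age = records["age_first_repro_d"].to_numpy()
    clutch = records["clutch_size"].to_numpy()
    survived = records["survived"].to_numpy()

    if point_fit is None:
        robs = compute_r_observations(records, lx_scope=lx_scope)
        point_fit = _FITTERS[model_tag](
            robs["concentration_mgC_per_L"].to_numpy(), robs["r"].to_numpy())

    strata = _stratum_indices(conc_all)
    lx_fixed = {i: survived[s].mean() for i, s in enumerate(strata)}

    def draw(_i, rng):
        xs, rs = [], []
        for si, s in enumerate(strata):
            idx = s[rng.integers(0, s.size, s.size)]
            lx = survived[idx].mean() if config.lx_mode == "varying" else lx_fixed[si]
            keep = survived[idx] & (clutch[idx] >= 1)
            if lx <= 0 or not keep.any():
                continue
            kidx = idx[keep]
            rs.append(_euler_lotka_closed_form(age[kidx], lx, clutch[kidx]))
            xs.append(conc_all[kidx])
        if not xs:
            raise InferenceFailureError("resample contains no reproducing animals")
        return np.concatenate(xs), np.concatenate(rs)

    return _bootstrap_fit_loop(None, draw, point_fit, model_tag, config)


def _require_single_clone(records: pd.DataFrame):
    clones = records["clone_id"].unique()
    if clones.size != 1:
        raise InvalidInputError(
            f"bootstrap operates on one clone at a time, got {list(clones)}")


@dataclass
class CloneOrdering:
    """CI-overlap partial order over clones.

    ``clones`` are sorted by interval lower bound; ``relations`` holds the
    symbol ('<' or '=') between each consecutive pair. Chained overlaps are
    reported as-is; no transitive closure is taken.
    """

    clones: list[str]
    relations: list[str]
    intervals: dict[str, ConfidenceInterval] = field(default_factory=dict)

    def __str__(self) -> str:
        parts = [self.clones[0]]
        for sym, clone in zip(self.relations, self.clones[1:]):
            parts += [sym, clone]
        return " ".join(parts)

    def strictly_less(self, a: str, b: str) -> bool:
        """True iff a's interval lies entirely below b's."""
        return self.intervals[a].upper < self.intervals[b].lower


def compare_by_ci(cis: dict[str, ConfidenceInterval]) -> CloneOrdering:
    """Order clones by confidence-interval overlap.

    Clones are sorted by CI lower bound (upper bound breaking ties); each
    consecutive pair is separated by '<' when the intervals are disjoint
    and '=' when they overlap. The rendered string follows the field's
    reporting convention, e.g. ``"B3 = B2 < D2 = D4"``.
    """
    if len(cis) < 2:
        raise InvalidInputError("need >= 2 clones to compare")
    order = sorted(cis, key=lambda c: (cis[c].lower, cis[c].upper))
    relations = []
    for a, b in zip(order, order[1:]):
        relations.append("<" if cis[a].upper < cis[b].lower else "=")
    return CloneOrdering(order, relations, dict(cis))
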