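"""Per-individual life-history traits: somatic growth rate and early-life r.

Somatic growth rate is the per-day mass-specific growth from birth to first
reproduction, ``g = (ln M_t - ln M_0) / t``. The intrinsic rate of increase
``r`` solves the Euler-Lotka equation ``1 = sum e^{-r x} l_x m_x`` over the
age schedule; here the schedule has a single event — first reproduction at
age ``x`` with clutch size ``m_x`` and cohort survival ``l_x`` — so the
equation reduces to ``e^{-r x} l_x m_x = 1`` and the numerical solution must
agree with the closed form ``ln(l_x m_x) / x``. This is an early-life r: it
captures population growth potential up to the first clutch, not lifetime
reproduction.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import InvalidInputError, UndefinedRError
from .records import check_records

__all__ = [
    "somatic_growth_rate",
    "cohort_survival",
    "solve_euler_lotka",
    "growth_observations",
    "compute_r_observations",
]

logger = logging.getLogger(__name__)

_STRATUM = ["clone_id", "concentration_mgC_per_L"]


def somatic_growth_rate(initial_mass, final_mass, duration):
    """Per-day somatic growth rate ``(ln M_t - ln M_0) / t``.

    Accepts scalars or arrays; masses must be positive and duration
    strictly positive. Negative rates (mass loss near starvation) are
    legitimate output.
    """
    m0 = np.asarray(initial_mass, dtype=float)
    mt = np.asarray(final_mass, dtype=float)
    t = np.asarray(duration, dtype=float)
    if np.any(m0 <= 0) or np.any(mt <= 0):
        raise InvalidInputError("masses must be positive")
    if np.any(t <= 0):
        raise InvalidInputError("duration must be positive")
    g = (np.log(mt) - np.log(m0)) / t
    return float(g) if g.ndim == 0 else g


def cohort_survival(records: pd.DataFrame, scope: str = "stratum") -> pd.DataFrame:
    """Survival to first reproduction per clone x concentration stratum.

    ``l_x`` is the fraction of animals in the stratum that survived to
    carry eggs. With ``scope="clone"`` survival is pooled across
    concentrations within each clone and broadcast back to its strata.
    """
    records = check_records(records)
    grouped = records.groupby(_STRATUM, sort=True)
    out = grouped["survived"].agg(n_total="size", n_reproduced="sum").reset_index()
    if scope == "clone":
        clone_lx = (records.groupby("clone_id")["survived"].mean()
                    .rename("l_x").reset_index())
        out = out.merge(clone_lx, on="clone_id")
    elif scope == "stratum":
        out["l_x"] = out["n_reproduced"] / out["n_total"]
    else:
        raise InvalidInputError(f"unknown l_x scope {scope!r}")
    return out


def solve_euler_lotka(x: float, l_x: float, m_x: float,
                      tol: float = 1e-10) -> float:
    """Numerically solve ``e^{-r x} l_x m_x = 1`` for r (day^-1).

    Bracketed root-finding on r in [-5, 5] day^-1, with the bracket
    doubled until a sign change (capped at +/-50). For this single-event
    schedule the exact solution is ``ln(l_x * m_x) / x``; the numerical
    root matches it to well below 1e-8.

    Raises
    ------
    UndefinedRError
        If ``l_x * m_x <= 0`` (no reproduction: the equation has no root).
    InvalidInputError
        If ``x <= 0`` or ``l_x`` outside (0, 1].
    """
    if not (x > 0):
        raise InvalidInputError(f"age at first reproduction must be positive, got {x}")
    if not (0 < l_x <= 1):
        raise InvalidInputError(f"l_x must be in (0, 1], got {l_x}")
    lm = l_x * m_x
    if lm <= 0:
        raise UndefinedRError(
            f"l_x * m_x = {lm} <= 0: r is undefined for this individual")

    def f(r):
        return math.exp(-r * x) * lm - 1.0

    lo, hi = -5.0, 5.0
    while f(lo) * f(hi) > 0:
        lo, hi = max(lo * 2, -50.0), min(hi * 2, 50.0)
        if lo == -50.0 and hi == 50.0 and f(lo) * f(hi) > 0:
            raise UndefinedRError("no root for r in [-50, 50] day^-1")
    return float(brentq(f, lo, hi, xtol=tol))


def _euler_lotka_closed_form(x, l_x, m_x):
    """Vectorized exact r for the single-event schedule: ln(l_x m_x)/x."""
    return np.log(np.asarray(l_x, dtype=float) * np.asarray(m_x, dtype=float)) \
        / np.asarray(x, dtype=float)


def growth_observations(records: pd.DataFrame) -> pd.DataFrame:
    """Per-individual somatic growth rates for all animals that reproduced.

    Animals that died before first reproduction have no final mass and are
    excluded (they still enter ``cohort_survival``). Returns columns
    clone_id, concentration_mgC_per_L, g.
    """
    records = check_records(records)
    surv = records[records["survived"]].copy()
    if surv.empty:
        return pd.DataFrame(columns=_STRATUM + ["g"])
    surv["g"] = somatic_growth_rate(
        surv["initial_mass_ug"].to_numpy(),
        surv["final_mass_ug"].to_numpy(),
        surv["age_first_repro_d"].to_numpy(),
    )
    return surv[_STRATUM + ["g"]].reset_index(drop=True)


def compute_r_observations(records: pd.DataFrame,
                           lx_scope: str = "stratum") -> pd.DataFrame:
    """Per-individual early-life r, using stratum-level survival.

    Each surviving animal with at least one egg contributes one observation:
    its own age at first reproduction ``x`` and clutch size ``m_x`` combined
    with the cohort survival ``l_x`` of its stratum (or clone, per
    ``lx_scope``). Non-survivors and zero-clutch animals contribute to
    ``l_x`` but yield no r observation; the skips are logged, never raised.

    Returns columns clone_id, concentration_mgC_per_L, r, x, m_x, l_x_used.
    """
    records = check_records(records)
    lx = cohort_survival(records, scope=lx_scope)[_STRATUM + ["l_x"]]
    merged = records.merge(lx, on=_STRATUM, how="left")

    repro = merged["survived"] & (merged["clutch_size"] >= 1)
    n_skipped = int((~repro).sum())
    if n_skipped:
        logger.info("r: skipping %d individuals (died or zero clutch); "
                    "they still enter l_x", n_skipped)

    sub = merged[repro]
    rows = []
    for row in sub.itertuples(index=False):
        try:
            r = solve_euler_lotka(row.age_first_repro_d, row.l_x, row.clutch_size)
        except UndefinedRError as exc:  # l_x could be 0 only if no survivors
            logger.warning("r undefined for clone %s at %.4g mg C/L: %s",
                           row.clone_id, row.concentration_mgC_per_L, exc)
            continue
        rows.append((row.clone_id, row.concentration_mgC_per_L, r,
                     row.age_first_repro_d, row.clutch_size, row.l_x))
    return pd.DataFrame(
        rows, columns=_STRATUM + ["r", "x", "m_x", "l_x_used"]
    )
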