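"""Saturation-curve (plateau) models for trait-vs-food-concentration data.

Two segmented mean functions are provided, both with three free parameters:

* **Quadratic plateau** — a concave-down quadratic that rises from an
  intercept ``b0`` with initial slope ``b1`` and joins a flat plateau
  *smoothly* (zero slope) at the break-point ``cx``. The quadratic
  coefficient is not free: ``b2 = -b1 / (2 cx)`` is the unique value that
  makes the derivative vanish at the join, so the plateau height is
  ``b0 + b1 cx / 2``.

* **Hockey stick** — a piecewise-linear alternative,
  ``y = b0 + b1 * min(x, cx)``, continuous at ``cx`` but with an abrupt
  slope change; plateau height ``b0 + b1 cx``.

In the food-limitation literature the fitted break-point is the *incipient
limiting level* (ILL): the food concentration above which the trait no
longer increases. The x-intercept of the rising branch, where predicted
performance is zero, is the *threshold food level* (TFL).

Fitting is nonlinear least squares over ``(b0, b1, cx)``. Both models are
partially linear: at fixed ``cx`` they are ordinary least squares in
``(b0, b1)``, which this module exploits for starting values, for a cheap
global check after the primary optimizer, and for the independent
profile-grid oracle used in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InsufficientDesignError, InvalidInputError, NonConvergenceError

__all__ = [
    "QuadraticPlateauParams",
    "HockeyStickParams",
    "PlateauFitResult",
    "DegenerateDataWarning",
    "quadplateau_predict",
    "hockeystick_predict",
    "selfstart_quadplateau",
    "fit_quadratic_plateau",
    "fit_hockey_stick",
    "derive_tfl",
    "profile_grid_oracle",
]

QUADRATIC_PLATEAU = "quadratic_plateau"
HOCKEY_STICK = "hockey_stick"


class DegenerateDataWarning(UserWarning):
    """Raised when the data carry no usable rising signal (e.g. flat y)."""


@dataclass(frozen=True)
class QuadraticPlateauParams:
    """Parameters of the smooth quadratic-plateau curve.

    Attributes
    ----------
    b0 : float
        Intercept (response at zero food).
    b1 : float
        Initial slope (response units per mg C L^-1).
    cx : float
        Break-point, the ILL (mg C_org L^-1); must be positive.
    """

    b0: float
    b1: float
    cx: float

    def __post_init__(self):
        if not np.isfinite(self.cx) or self.cx <= 0:
            raise InvalidInputError(f"break-point cx must be positive, got {self.cx}")

    @property
    def b2(self) -> float:
        """Derived quadratic coefficient enforcing a zero-slope join at cx."""
        return -self.b1 / (2.0 * self.cx)

    @property
    def plateau(self) -> float:
        """Plateau elevation, the predicted response at the break-point."""
        return self.b0 + self.b1 * self.cx / 2.0


@dataclass(frozen=True)
class HockeyStickParams:
    """Parameters of the piecewise-linear (hockey-stick) curve."""

    b0: float
    b1: float
    cx: float

    def __post_init__(self):
        if not np.isfinite(self.cx) or self.cx <= 0:
            raise InvalidInputError(f"break-point cx must be positive, got {self.cx}")

    @property
    def plateau(self) -> float:
        return self.b0 + self.b1 * self.cx


@dataclass
class PlateauFitResult:
    """Outcome of a plateau-model fit.

    ``tfl`` is ``None`` when the fitted curve never crosses zero on the
    rising branch (not-estimable is a value, not an error). ``at_boundary``
    flags break-point estimates pinned at the largest observed
    concentration, where the plateau is not identified by the data.
    """

    params: QuadraticPlateauParams | HockeyStickParams
    ill: float
    plateau_elevation: float
    tfl: float | None
    rss: float
    n_obs: int
    converged: bool
    model_tag: str
    optimizer_tag: str
    at_boundary: bool = False
    diagnostics: dict = field(default_factory=dict)


def quadplateau_predict(params: QuadraticPlateauParams, x) -> np.ndarray | float:
    """Evaluate the quadratic-plateau curve at concentration(s) ``x``.

    Rising branch ``b0 + b1 x + b2 x**2`` for ``x <= cx``, constant plateau
    beyond.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("concentration x must be >= 0")
    xr = np.minimum(x, params.cx)
    y = params.b0 + params.b1 * xr + params.b2 * xr * xr
    return float(y) if y.ndim == 0 else y


def hockeystick_predict(params: HockeyStickParams, x) -> np.ndarray | float:
    """Evaluate the hockey-stick curve at concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidInputError("concentration x must be >= 0")
    y = params.b0 + params.b1 * np.minimum(x, params.cx)
    return float(y) if y.ndim == 0 else y


def _as_xy(data, x=None):
    """Accept either ``(x_array, y_array)`` or a sequence of (x, y) pairs."""
    if x is not None:
        return np.asarray(data, dtype=float), np.asarray(x, dtype=float)
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    raise InvalidInputError("data must be (x, y) arrays or a sequence of pairs")


def _check_design(x, y, min_points=6):
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("x and y must be finite")
    if np.any(x < 0):
        raise InvalidInputError("concentrations must be non-negative")
    n_levels = np.unique(x).size
    if n_levels < 4:
        raise InsufficientDesignError(
            f"need >= 4 distinct concentration levels, got {n_levels}")
    if x.size < min_points:
        raise InsufficientDesignError(
            f"need >= {min_points} observations, got {x.size}")


def _rising_basis(x, cx, model_tag):
    """Column h(x; cx) such that the mean function is b0 + b1 * h."""
    if model_tag == QUADRATIC_PLATEAU:
        xr = np.minimum(x, cx)
        return xr - xr * xr / (2.0 * cx)
    return np.minimum(x, cx)


def _profile_ols(x, y, cx_grid, model_tag):
    """Vectorized OLS of y on [1, h(x; cx)] for every cx in ``cx_grid``.

    Returns (b0, b1, rss) arrays over the grid. Grid points at which the
    basis column is collinear with the intercept (all x on the plateau
    branch of a degenerate cx) get rss = inf.
    """
    x = x[None, :]
    cx = np.asarray(cx_grid, dtype=float)[:, None]
    if model_tag == QUADRATIC_PLATEAU:
        xr = np.minimum(x, cx)
        h = xr - xr * xr / (2.0 * cx)
    else:
        h = np.minimum(x, cx)
    n = x.shape[1]
    sy = float(np.sum(y))
    syy = float(np.dot(y, y))
    sh = h.sum(axis=1)
    shh = np.einsum("ij,ij->i", h, h)
    shy = h @ y
    det = n * shh - sh * sh
    ok = det > 1e-12 * max(1.0, float(np.max(shh, initial=0.0))) * n
    b1 = np.zeros_like(sh)
    np.divide(n * shy - sh * sy, det, out=b1, where=ok)
    b0 = (sy - b1 * sh) / n
    rss = (syy + n * b0 * b0 + b1 * b1 * shh
           + 2.0 * b0 * b1 * sh - 2.0 * b0 * sy - 2.0 * b1 * shy)
    rss = np.maximum(rss, 0.0)
    rss[~ok] = np.inf
    return b0.ravel(), b1.ravel(), rss.ravel()


def selfstart_quadplateau(data, y=None) -> QuadraticPlateauParams:
    """Deterministic self-starting values for the quadratic-plateau fit.

    Recipe: the plateau guess is the mean response over the two highest
    concentration levels; the initial slope and intercept come from a
    least-squares line through the points below the median concentration;
    the break-point guess is where that line reaches the plateau guess,
    clamped into (smallest positive concentration, largest concentration].
    """
    x, yv = _as_xy(data, y)
    _check_design(x, yv, min_points=4)
    levels = np.unique(x)
    top = np.isin(x, levels[-2:])
    plateau0 = float(np.mean(yv[top]))

    med = float(np.median(x))
    low = x < med
    if low.sum() >= 2 and np.ptp(x[low]) > 0:
        slope0, intercept0 = np.polyfit(x[low], yv[low], 1)
    else:
        slope0, intercept0 = 0.0, float(np.mean(yv[low])) if low.any() else plateau0

    positive = levels[levels > 0]
    x_lo = float(positive[0]) if positive.size else float(levels[0])
    x_hi = float(levels[-1])
    slope_floor = 1e-10 * max(1.0, float(np.ptp(yv)) / max(float(np.ptp(x)), 1e-12))
    if not np.isfinite(slope0) or slope0 <= slope_floor:
        warnings.warn("flat or declining data: self-start is degenerate",
                      DegenerateDataWarning, stacklevel=2)
        slope0 = 0.0
        cx0 = x_hi
        intercept0 = plateau0
    else:
        cx0 = float(np.clip((plateau0 - intercept0) / slope0, x_lo, x_hi))
    return QuadraticPlateauParams(b0=float(intercept0), b1=float(slope0), cx=cx0)


def _residual_and_jac(model_tag):
    if model_tag == QUADRATIC_PLATEAU:
        def fun(theta, x, y):
            b0, b1, cx = theta
            xr = np.minimum(x, cx)
            return b0 + b1 * (xr - xr * xr / (2.0 * cx)) - y

        def jac(theta, x, y):
            b0, b1, cx = theta
            xr = np.minimum(x, cx)
            J = np.empty((x.size, 3))
            J[:, 0] = 1.0
            J[:, 1] = xr - xr * xr / (2.0 * cx)
            J[:, 2] = b1 * np.where(x <= cx, x * x / (2.0 * cx * cx), 0.5)
            return J
    else:
        def fun(theta, x, y):
            b0, b1, cx = theta
            return b0 + b1 * np.minimum(x, cx) - y

        def jac(theta, x, y):
            b0, b1, cx = theta
            J = np.empty((x.size, 3))
            J[:, 0] = 1.0
            J[:, 1] = np.minimum(x, cx)
            J[:, 2] = np.where(x > cx, b1, 0.0)
            return J
    return fun, jac


def _run_ls(x, y, theta0, model_tag, cx_hi, max_nfev=None):
    fun, jac = _residual_and_jac(model_tag)
    cx_lo = 1e-10
    theta0 = np.array([theta0[0], theta0[1], float(np.clip(theta0[2], cx_lo, cx_hi))])
    res = least_squares(
        fun, theta0, jac=jac, args=(x, y), method="trf",
        bounds=([-np.inf, -np.inf, cx_lo], [np.inf, np.inf, cx_hi]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=max_nfev,
    )
    rss = float(2.0 * res.cost)
    return res.x, rss, bool(res.success)


def _package_result(theta, rss, x, model_tag, optimizer_tag, converged,
                    diagnostics=None) -> PlateauFitResult:
    b0, b1, cx = (float(v) for v in theta)
    cx_hi = float(np.max(x))
    at_boundary = cx >= cx_hi * (1.0 - 1e-6)
    if model_tag == QUADRATIC_PLATEAU:
        params = QuadraticPlateauParams(b0=b0, b1=b1, cx=cx)
    else:
        params = HockeyStickParams(b0=b0, b1=b1, cx=cx)
    return PlateauFitResult(
        params=params,
        ill=cx,
        plateau_elevation=params.plateau,
        tfl=derive_tfl(params),
        rss=float(rss),
        n_obs=int(x.size),
        converged=converged,
        model_tag=model_tag,
        optimizer_tag=optimizer_tag,
        at_boundary=at_boundary,
        diagnostics=diagnostics or {},
    )


_SCAN_SLACK = 1e-9  # relative RSS slack before the grid fallback is invoked


def _fit(data, y, model_tag, start=None) -> PlateauFitResult:
    x, yv = _as_xy(data, y)
    _check_design(x, yv)
    cx_hi = float(np.max(x))

    if start is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            s = selfstart_quadplateau(x, yv)
        theta0 = (s.b0, max(s.b1, 1e-8), s.cx)
    else:
        theta0 = (start.b0, start.b1, start.cx)

    primary_theta, primary_rss, primary_ok = None, np.inf, False
    try:
        primary_theta, primary_rss, primary_ok = _run_ls(x, yv, theta0, model_tag, cx_hi)
    except Exception:
        primary_ok = False

    # Cheap global check: profiled RSS on the fallback grid. If a grid point
    # beats the primary solution the primary is treated as failed (stuck in a
    # local minimum) and the full multi-start fallback runs.
    grid = np.geomspace(max(np.min(x[x > 0], initial=cx_hi), 1e-6), cx_hi, 20)
    gb0, gb1, grss = _profile_ols(x, yv, grid, model_tag)
    best_grid = int(np.argmin(grss))
    need_fallback = (not primary_ok) or (
        np.isfinite(grss[best_grid])
        and grss[best_grid] < primary_rss * (1.0 - _SCAN_SLACK) - _SCAN_SLACK
    )

    if not need_fallback:
        return _package_result(primary_theta, primary_rss, x, model_tag,
                               "primary", True)

    candidates = []
    if primary_ok:
        candidates.append((primary_theta, primary_rss))
    for i in range(grid.size):
        if not np.isfinite(grss[i]):
            continue
        try:
            th, rss, ok = _run_ls(x, yv, (gb0[i], gb1[i], grid[i]), model_tag, cx_hi)
        except Exception:
            continue
        if ok:
            candidates.append((th, rss))
    if not candidates:
        raise NonConvergenceError(
            "no optimizer start converged",
            diagnostics={"selfstart": theta0, "grid_rss": grss})
    # lowest RSS wins; ties broken toward the smallest break-point
    best_rss = min(rss for _, rss in candidates)
    tol = max(abs(best_rss), 1.0) * 1e-12
    best = min((c for c in candidates if c[1] <= best_rss + tol),
               key=lambda c: c[0][2])
    return _package_result(best[0], best[1], x, model_tag, "fallback", True)


def fit_quadratic_plateau(data, y=None, start=None) -> PlateauFitResult:
    """Fit the quadratic-plateau model by nonlinear least squares.

    Parameters
    ----------
    data, y
        Either two 1-d arrays ``(x, y)`` or a single sequence of (x, y)
        pairs. ``x`` are food concentrations (mg C_org L^-1), ``y`` the
        trait values (e.g. somatic growth rate, day^-1).
    start : QuadraticPlateauParams, optional
        Warm start; when omitted the deterministic self-starter is used.

    The primary optimizer is a trust-region-reflective damped least-squares
    run from the starting values, with the break-point constrained to
    (0, max observed x]. If it fails — including landing above the best
    point of a 20-point log-spaced profiled-RSS scan — a multi-start
    fallback runs damped least squares from every grid point and keeps the
    lowest RSS (ties broken toward the smaller break-point). The result
    records which path produced it.
    """
    return _fit(data, y, QUADRATIC_PLATEAU, start=start)


def fit_hockey_stick(data, y=None, start=None) -> PlateauFitResult:
    """Fit the piecewise-linear (hockey-stick) model; see fit_quadratic_plateau."""
    return _fit(data, y, HOCKEY_STICK, start=start)


def derive_tfl(params) -> float | None:
    """Threshold food level: x-intercept of the rising branch, or ``None``.

    For the quadratic plateau this solves ``b0 + b1 x + b2 x**2 = 0`` and
    returns the smaller root when it lies in [0, cx]; for the hockey stick
    it is ``-b0/b1`` under the same containment. A curve already positive
    at zero food (b0 > 0), or with no real root on the rising branch, has
    no estimable TFL and returns ``None``.
    """
    b0, b1, cx = params.b0, params.b1, params.cx
    if b0 > 0:
        return None
    if b0 == 0:
        return 0.0
    if b1 <= 0:
        return None
    if isinstance(params, HockeyStickParams):
        tfl = -b0 / b1
        return float(tfl) if tfl < cx else None
    b2 = params.b2
    disc = b1 * b1 - 4.0 * b2 * b0
    if disc < 0:
        return None
    root = (-b1 + np.sqrt(disc)) / (2.0 * b2)  # smaller root (b2 < 0)
    if 0.0 <= root <= cx:
        return float(root)
    return None


def profile_grid_oracle(data, y=None, cx_grid=None,
                        model_tag: str = QUADRATIC_PLATEAU) -> PlateauFitResult:
    """Brute-force plateau fit by profiling the break-point over a grid.

    At each fixed cx the model is linear in (b0, b1), so each grid point is
    an ordinary least-squares solve; the global minimum over the grid is
    returned. Independent of the iterative optimizer, this serves as a
    cross-check oracle: its minimized RSS can exceed the optimizer's by at
    most the grid-resolution effect.
    """
    x, yv = _as_xy(data, y)
    _check_design(x, yv)
    if cx_grid is None:
        cx_grid = np.linspace(np.min(x[x > 0]) if np.any(x > 0) else 1e-6,
                              float(np.max(x)), 1000)
    cx_grid = np.asarray(cx_grid, dtype=float)
    if cx_grid.size < 1 or np.any(cx_grid <= 0):
        raise InvalidInputError("cx_grid must be positive")
    b0, b1, rss = _profile_ols(x, yv, cx_grid, model_tag)
    if not np.any(np.isfinite(rss)):
        raise NonConvergenceError("profile grid produced no valid fit")
    best_rss = np.min(rss)
    tol = max(abs(best_rss), 1.0) * 1e-12
    i = int(np.argmax(rss <= best_rss + tol))  # smallest cx among ties
    return _package_result((b0[i], b1[i], cx_grid[i]), rss[i], x, model_tag,
                           "grid_oracle", True)
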