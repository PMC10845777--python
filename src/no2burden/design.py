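"""Regression design components for county time-series models.

Natural cubic spline bases (R ``ns``-style: explicit interior knots, zero
second derivative at the boundary knots, linear extrapolation beyond them),
lagged-exposure matrices, trailing moving averages, and calendar indicator
columns. Everything returns pandas objects aligned to the input index so the
county model can assemble a single design matrix by concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis",
    "LagSpec",
    "ns_basis",
    "lag_matrix",
    "calendar_design",
    "moving_average",
]


def _bspline_columns(x: np.ndarray, t: np.ndarray, nu: int = 0) -> np.ndarray:
    """Evaluate every cubic B-spline defined by knot vector ``t`` (or its
    ``nu``-th derivative) at the points ``x``."""
    n_basis = len(t) - 4
    out = np.empty((len(x), n_basis))
    for j in range(n_basis):
        c = np.zeros(n_basis)
        c[j] = 1.0
        out[:, j] = BSpline(t, c, 3)(x, nu=nu)
    return out


@dataclass(frozen=True)
class SplineBasis:
    """A natural cubic spline basis evaluated on a data vector.

    The basis has ``df`` columns, is linear outside the boundary knots and
    can be re-evaluated at new points (needed when pooling
    concentration-response curves on a common grid).
    """

    df: int
    knots: np.ndarray          # interior knots, sorted
    boundary: tuple[float, float]
    matrix: np.ndarray         # n x df
    _transform: np.ndarray = field(repr=False)  # (m+3) x df projection

    @property
    def full_knot_vector(self) -> np.ndarray:
        a, b = self.boundary
        return np.sort(np.concatenate([[a] * 4, self.knots, [b] * 4]))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the basis at new points, linear beyond the boundaries."""
        x = np.asarray(x, dtype=float)
        t = self.full_knot_vector
        a, b = self.boundary
        inside = np.clip(x, a, b)
        raw = _bspline_columns(inside, t)[:, 1:]
        # first-order Taylor extension outside the boundary knots: the
        # natural conditions make the extension exact
        lo, hi = x < a, x > b
        if lo.any():
            d = _bspline_columns(np.array([a]), t, nu=1)[:, 1:]
            raw[lo] += (x[lo] - a)[:, None] * d
        if hi.any():
            d = _bspline_columns(np.array([b]), t, nu=1)[:, 1:]
            raw[hi] += (x[hi] - b)[:, None] * d
        return raw @ self._transform


def ns_basis(
    x,
    df: int,
    knots=None,
    boundary=None,
) -> SplineBasis:
    """Natural cubic spline basis with ``df`` columns (no intercept).

    Interior knots default to the i/df quantiles (i = 1..df-1) of the
    *unique* values of ``x``; boundary knots default to min/max. Explicit
    ``knots`` override quantile placement (the concentration-response model
    passes 20 and 40 ug/m3).

    Raises
    ------
    ValueError
        If ``df < 1`` or there are not enough distinct values to support
        ``df`` columns (rank deficiency).
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    uniq = np.unique(x)
    if len(uniq) <= df:
        raise ValueError(
            f"rank deficiency: df={df} requires more than {df} distinct "
            f"values, got {len(uniq)}"
        )
    if boundary is None:
        boundary = (float(uniq[0]), float(uniq[-1]))
    a, b = map(float, boundary)
    if knots is None:
        probs = np.arange(1, df) / df
        interior = np.quantile(uniq, probs) if df > 1 else np.empty(0)
    else:
        interior = np.sort(np.asarray(knots, dtype=float))
        if len(interior) != df - 1:
            raise ValueError(
                f"{len(interior)} interior knots imply df={len(interior) + 1}, "
                f"but df={df} was requested"
            )
    if len(interior) and (interior[0] <= a or interior[-1] >= b):
        raise ValueError("interior knots must lie strictly inside the boundary knots")

    t = np.sort(np.concatenate([[a] * 4, interior, [b] * 4]))
    # drop the leading B-spline (intercept), then project the remaining
    # m+3 columns onto the null space of the two boundary second-derivative
    # constraints -> m+1 = df natural columns
    const = _bspline_columns(np.array([a, b]), t, nu=2)[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    transform = q[:, 2:]
    raw = _bspline_columns(np.clip(x, a, b), t)[:, 1:]
    basis = SplineBasis(
        df=df,
        knots=interior,
        boundary=(a, b),
        matrix=np.empty(0),
        _transform=transform,
    )
    object.__setattr__(basis, "matrix", basis.evaluate(x))
    return basis


@dataclass(frozen=True)
class LagSpec:
    """Exposure lag structure: single-day lags entered jointly, cumulative
    sums of those lags, or one trailing moving-average column."""

    kind: str = "single"       # single | cumulative | moving_average
    max_lag: int = 4

    def __post_init__(self):
        if self.kind not in {"single", "cumulative", "moving_average"}:
            raise ValueError(f"unknown lag kind {self.kind!r}")
        if self.max_lag not in {0, 1, 2, 3, 4}:
            raise ValueError(f"max_lag must be in 0..4, got {self.max_lag}")

    @property
    def label(self) -> str:
        if self.kind == "moving_average":
            return f"lag0-{self.max_lag} MA"
        return f"lag0-{self.max_lag}"


def lag_matrix(series, spec: LagSpec) -> tuple[pd.DataFrame, list[int]]:
    """Lagged-exposure design columns.

    For ``single``/``cumulative`` the columns are the series shifted by
    0..max_lag (lag 0 is the same day, lag 1 the previous day). For
    ``moving_average`` there is one column: the mean of lags 0..max_lag.
    Returns the matrix and the positions of the leading rows that have no
    complete lag history.
    """
    s = pd.Series(np.asarray(series, dtype=float))
    if len(s) <= spec.max_lag:
        raise ValueError(
            f"series of length {len(s)} too short for max_lag={spec.max_lag}"
        )
    lags = pd.DataFrame(
        {f"lag{l}": s.shift(l) for l in range(spec.max_lag + 1)}
    )
    if spec.kind == "moving_average":
        out = lags.mean(axis=1).to_frame(name=f"ma0_{spec.max_lag}")
        out[lags.isna().any(axis=1)] = np.nan
    else:
        out = lags
    return out, list(range(spec.max_lag))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def calendar_design(dates, holidays=None, n_years: float | None = None) -> pd.DataFrame:
    """Day-of-week indicators (reference Monday), a holiday indicator, and a
    natural spline in the day index with round(7 x n_years) df.

    ``holidays`` may be a set of dates or a boolean series aligned to
    ``dates``. ``n_years`` defaults to n_days / 365.25.
    """
    dates = pd.DatetimeIndex(dates)
    if len(dates) > 1:
        gaps = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if not np.all(gaps == 1):
            bad = dates[1:][gaps != 1]
            raise ValueError(f"dates must be consecutive; gap before {bad[0].date()}")
    n = len(dates)
    if n_years is None:
        n_years = n / 365.25
    out = {}
    dow = dates.dayofweek  # Monday = 0
    names = ["tue", "wed", "thu", "fri", "sat", "sun"]
    for i, name in enumerate(names, start=1):
        out[f"dow_{name}"] = (dow == i).astype(float)
    if holidays is None:
        hol = np.zeros(n)
    elif isinstance(holidays, (pd.Series, np.ndarray, list)) and len(holidays) == n:
        hol = np.asarray(holidays, dtype=float)
    else:
        hol = np.array([d in holidays for d in dates.date], dtype=float)
    out["holiday"] = hol
    df_time = max(1, _round_half_up(7.0 * n_years))
    tb = ns_basis(np.arange(n, dtype=float), df=df_time)
    frame = pd.DataFrame(out, index=dates)
    for j in range(df_time):
        frame[f"time_ns{j + 1}"] = tb.matrix[:, j]
    return frame


def moving_average(series, window: int = 3) -> pd.Series:
    """Trailing moving average: value at day t is the mean of days
    t, t-1, ..., t-window+1; the first window-1 values are missing."""
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    s = pd.Series(np.asarray(series, dtype=float))
    if len(s) < window:
        raise ValueError(f"series of length {len(s)} shorter than window {window}")
    return s.rolling(window).mean()
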