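"""Ordinary least squares for concentration-vs-ln(time) lines.

Two estimators: plain OLS with intercept (the workhorse for fitting
LC50 = a·ln(LT50) + b) and a through-origin variant used to compare
reported against calculated life expectancies.  Both are thin layers over
statsmodels; this module owns input validation, the degenerate-design
conventions, and the result containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateDesignError, InsufficientDataError


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept fit of y on x with coefficient of determination.

    For a constant response (zero total sum of squares) R² is reported as 0
    and `degenerate` is set; such fits signal a series whose LC50 does not
    change with exposure time, which is screened out of life-expectancy work.
    """

    slope_a: float
    intercept_b: float
    r_squared: float
    n_points: int
    se_slope: Optional[float] = None
    se_intercept: Optional[float] = None
    degenerate: bool = False


@dataclass(frozen=True)
class OriginFit:
    """No-intercept fit y = slope·x.

    R² is computed against the uncentred total sum of squares Σy², the
    standard convention for models without an intercept.
    """

    slope: float
    r_squared: float
    n_points: int
    se_slope: Optional[float] = None


def _as_xy(xy_pairs: Sequence[Tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(list(xy_pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a sequence of (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def fit_ols(xy_pairs: Sequence[Tuple[float, float]]) -> LinearFit:
    """Least-squares line y = a·x + b.

    Raises
    ------
    InsufficientDataError : fewer than 2 pairs.
    DegenerateDesignError : all x identical (slope unidentifiable).
    """
    x, y = _as_xy(xy_pairs)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 points, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all x values identical; slope is unidentifiable")

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        # constant response: slope 0 exactly, R^2 reported as 0 by convention
        return LinearFit(slope_a=0.0, intercept_b=float(y[0]), r_squared=0.0,
                         n_points=n, se_slope=0.0, se_intercept=0.0, degenerate=True)

    res = sm.OLS(y, sm.add_constant(x)).fit()
    b, a = res.params
    se_b, se_a = res.bse if n > 2 else (math.nan, math.nan)
    r2 = float(res.rsquared)
    # two distinct points define the line exactly
    if n == 2:
        r2 = 1.0
    return LinearFit(slope_a=float(a), intercept_b=float(b),
                     r_squared=min(max(r2, 0.0), 1.0), n_points=n,
                     se_slope=float(se_a), se_intercept=float(se_b))


def fit_through_origin(xy_pairs: Sequence[Tuple[float, float]]) -> OriginFit:
    """Least-squares proportionality y = slope·x (slope = Σxy / Σx²)."""
    x, y = _as_xy(xy_pairs)
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"need >= 2 points, got {n}")
    if np.all(x == 0):
        raise DegenerateDesignError("all x values are zero; slope is unidentifiable")
    res = sm.OLS(y, x).fit()
    r2 = float(res.rsquared)  # uncentred for no-constant models
    return OriginFit(slope=float(res.params[0]),
                     r_squared=min(max(r2, 0.0), 1.0), n_points=n,
                     se_slope=float(res.bse[0]) if n > 1 else math.nan)
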