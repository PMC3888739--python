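"""Haber's rule and Warren's threshold equation as contrast models.

Haber's rule, C·t = k, asserts a constant concentration-time product for a
fixed effect; its predicted time diverges as the concentration approaches
zero.  Warren's form, (C − C0)·t = k, adds a no-effect threshold C0 below
which the predicted time is likewise infinite.  Both are fitted to the same
LC50-vs-time series the RLE model uses, so the three can be compared on the
concentration scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DivergenceError, InsufficientDataError, ValidationError
from .rle import fit_rle, predict_lc50
from .units_io import ToxicitySeries


@dataclass(frozen=True)
class HaberFit:
    """Constant concentration-time product k (µg·day/L)."""

    k_value: float


@dataclass(frozen=True)
class WarrenFit:
    """Threshold c0 (µg/L) and product k (µg·day/L), with the fit's RSS."""

    c0: float
    k_value: float
    rss: float


def fit_haber(series: ToxicitySeries, method: str = "geometric") -> HaberFit:
    """Estimate Haber's k from the per-record products c·t.

    The default is the geometric mean — least squares on the log scale with
    the slope fixed at −1, symmetric in c and t, and exact on ideal data.
    `method="arithmetic"` averages the raw products instead.
    """
    c = np.asarray(series.lc50s_ugL, dtype=float)
    t = np.asarray(series.times_days, dtype=float)
    if np.any(c <= 0):
        raise ValidationError("all concentrations must be > 0 for Haber's rule")
    products = c * t
    if method == "geometric":
        k = float(np.exp(np.mean(np.log(products))))
    elif method == "arithmetic":
        k = float(np.mean(products))
    else:
        raise ValidationError(f"unknown method: {method!r}")
    return HaberFit(k_value=k)


def fit_warren(series: ToxicitySeries) -> WarrenFit:
    """Least-squares fit of c = c0 + k/t with c0 constrained to be ≥ 0.

    The model is linear in (c0, k) once time enters as 1/t, so the
    concentration-scale objective Σ(c_i − c0 − k/t_i)² is minimized exactly
    by ordinary least squares of c on 1/t.  If the unconstrained threshold
    comes out negative, the constrained optimum sits on the boundary:
    c0 = 0 with k = Σ(c_i/t_i) / Σ(1/t_i²).
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 records for the two-parameter Warren fit, got {len(series)}")
    c = np.asarray(series.lc50s_ugL, dtype=float)
    inv_t = 1.0 / np.asarray(series.times_days, dtype=float)
    X = np.column_stack([np.ones_like(inv_t), inv_t])
    (c0, k), *_ = np.linalg.lstsq(X, c, rcond=None)
    if c0 < 0:
        c0 = 0.0
        k = float(np.sum(c * inv_t) / np.sum(inv_t ** 2))
    rss = float(np.sum((c - (c0 + k * inv_t)) ** 2))
    return WarrenFit(c0=float(c0), k_value=float(k), rss=rss)


def predict_time(model: "HaberFit | WarrenFit", conc_ugL: float) -> float:
    """Time to 50% lethality at a given concentration.

    Haber: t = k/c (asymptote at c = 0).  Warren: t = k/(c − c0) (asymptote
    at c = c0).  At or below the asymptote the predicted time is infinite
    and a DivergenceError names the offending threshold.
    """
    if isinstance(model, HaberFit):
        if conc_ugL <= 0:
            raise DivergenceError(
                "Haber's rule diverges at its asymptote c = 0 µg/L: predicted "
                "time is infinite at zero concentration")
        return model.k_value / conc_ugL
    if isinstance(model, WarrenFit):
        if conc_ugL <= model.c0:
            raise DivergenceError(
                f"Warren's equation diverges at its asymptote c = c0 = "
                f"{model.c0} µg/L")
        return model.k_value / (conc_ugL - model.c0)
    raise TypeError(f"unsupported model: {type(model).__name__}")


def compare_models(series: ToxicitySeries) -> pd.DataFrame:
    """Goodness of fit of the RLE, Haber and Warren models on one series.

    Returns one row per model with its parameters and the residual sum of
    squares on the concentration scale.  No information criteria are
    reported: with the typical 4 observations they would overreach.
    """
    c = np.asarray(series.lc50s_ugL, dtype=float)
    t = np.asarray(series.times_days, dtype=float)

    rle = fit_rle(series)
    rle_pred = np.array([rle.slope_a * math.log(ti) + rle.intercept_b for ti in t])
    rle_rss = float(np.sum((c - rle_pred) ** 2))

    haber = fit_haber(series)
    haber_rss = float(np.sum((c - haber.k_value / t) ** 2))

    warren = fit_warren(series)

    return pd.DataFrame([
        {"model": "RLE", "rss": rle_rss, "param_1": rle.slope_a,
         "param_2": rle.intercept_b, "params": "a, b"},
        {"model": "Haber", "rss": haber_rss, "param_1": haber.k_value,
         "param_2": math.nan, "params": "k"},
        {"model": "Warren", "rss": warren.rss, "param_1": warren.c0,
         "param_2": warren.k_value, "params": "c0, k"},
    ])
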