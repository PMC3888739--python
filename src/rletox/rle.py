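"""The reduced-life-expectancy (RLE) model of lethal toxicity.

The model treats exposure as shortening an organism's life expectancy:
the median lethal concentration falls linearly with the natural log of
the median lethal time,

    LC50 = a · ln(LT50) + b,        a < 0,

so the line's x-intercept, ln NLT = −b/a, is the normal life expectancy
(NLT) — the age at which half the cohort dies with no toxicant at all.
Unlike Haber's rule (C·t = k), whose predicted time diverges as the
concentration approaches zero, the RLE line pins the zero-concentration
limit at a finite, species-specific NLT.

The slope's reciprocal, d = −1/a, is the toxicity constant: the reduction
in log-scale life expectancy per unit concentration (µg/L).

Everything here works in the canonical units of `units_io`: µg/L and days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .errors import (
    InconsistentInputsError,
    InsufficientDataError,
    InsufficientDatasetsError,
    NegativeExtrapolationError,
    NoToxicityTrendError,
    ValidationError,
)
from .regression import LinearFit, OriginFit, fit_ols, fit_through_origin
from .units_io import ToxicitySeries

#: default R² below which a fit is flagged as departing from linearity
DEFAULT_R2_THRESHOLD = 0.8
#: default minimum number of datasets for a species-level NLT average
DEFAULT_MIN_DATASETS = 4

FLAG_LOW_R2 = "low_r2"
FLAG_NONNEG_SLOPE = "nonneg_slope"
FLAG_CONSTANT_LC50 = "constant_lc50"


@dataclass(frozen=True)
class RLEFit:
    """A fitted LC50-vs-ln(LT50) line for one species × toxicant dataset.

    Screen flags mark fits that fail the linearity screen (`low_r2`), show
    no toxicity trend (`nonneg_slope`), or have constant LC50 across times
    (`constant_lc50`).  Flagged fits are kept — the flags inform the caller;
    only the downstream life-expectancy operations reject them.
    """

    fit: LinearFit
    species: str = ""
    toxicant: str = ""
    screen_flags: frozenset[str] = field(default_factory=frozenset)
    method: str = "ols"

    @property
    def slope_a(self) -> float:
        return self.fit.slope_a

    @property
    def intercept_b(self) -> float:
        return self.fit.intercept_b

    @property
    def r_squared(self) -> float:
        return self.fit.r_squared


@dataclass(frozen=True)
class NLTEstimate:
    """Normal life expectancy on the log and natural scales.

    `method` records how it was obtained: from a single fitted line
    (`single_fit`), from the two-point construction (`two_point`), or by
    averaging per-dataset values within a species (`species_average`).
    """

    ln_nlt: float
    nlt_days: float
    method: str
    n_datasets: int = 1


@dataclass(frozen=True)
class ToxicityConstant:
    """d = −1/a: log-scale life-expectancy reduction per µg/L."""

    d_value: float


@dataclass(frozen=True)
class LC50Prediction:
    """Predicted lethal concentration at a given exposure time."""

    lc50_ugL: float
    t_days: float
    beyond_nlt: bool = False


@dataclass(frozen=True)
class RLEPrediction:
    """Predicted median lethal time at a given ambient concentration."""

    concentration_ugL: float
    lt50_days: float
    fraction_of_nlt: float


@dataclass(frozen=True)
class NLTComparison:
    """Through-origin regressions of reported on calculated NLT.

    Both the day scale and the ln(day) scale are reported; conventions in
    the literature differ and neither is privileged here.
    """

    day_scale: OriginFit
    ln_scale: OriginFit
    n_species: int


def fit_rle(series: ToxicitySeries, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> RLEFit:
    """Fit LC50 (µg/L) against ln(exposure time in days) by OLS.

    The fit is never silently discarded: screening outcomes (low R²,
    non-negative slope, constant LC50) are returned as flags.
    """
    times = series.times_days
    if len(set(times)) < 2:
        raise InsufficientDataError(
            f"{series.species}/{series.toxicant}: need >= 2 distinct exposure times")
    pairs = [(math.log(t), c) for t, c in zip(times, series.lc50s_ugL)]
    fit = fit_ols(pairs)
    flags = set()
    if fit.degenerate:
        flags.add(FLAG_CONSTANT_LC50)
    if fit.slope_a >= 0:
        flags.add(FLAG_NONNEG_SLOPE)
    if fit.r_squared < r2_threshold:
        flags.add(FLAG_LOW_R2)
    return RLEFit(fit=fit, species=series.species, toxicant=series.toxicant,
                  screen_flags=frozenset(flags))


def _coeffs(fit: "RLEFit | LinearFit") -> tuple[float, float]:
    if isinstance(fit, RLEFit):
        return fit.slope_a, fit.intercept_b
    return fit.slope_a, fit.intercept_b


def ln_nlt_from_fit(fit: "RLEFit | LinearFit") -> NLTEstimate:
    """Extrapolate the fitted line to LC50 = 0: ln NLT = −b/a.

    Requires a genuine toxicity trend (a < 0) and a positive intercept;
    otherwise the x-intercept does not correspond to a life expectancy.
    """
    a, b = _coeffs(fit)
    if a >= 0:
        raise NoToxicityTrendError(f"slope must be negative, got a={a}")
    if b <= 0:
        raise NegativeExtrapolationError(f"intercept must be positive, got b={b}")
    ln_nlt = -b / a
    return NLTEstimate(ln_nlt=ln_nlt, nlt_days=math.exp(ln_nlt), method="single_fit")


def toxicity_constant(fit: "RLEFit | LinearFit") -> ToxicityConstant:
    """d = −1/a, the life-expectancy reduction per unit concentration."""
    a, _ = _coeffs(fit)
    if a >= 0:
        raise NoToxicityTrendError(f"slope must be negative, got a={a}")
    return ToxicityConstant(d_value=-1.0 / a)


def predict_lc50(fit: "RLEFit | LinearFit", t_days: float) -> LC50Prediction:
    """Lethal concentration at exposure time `t_days`: a·ln(t) + b.

    Beyond the extrapolated NLT the line goes negative; the prediction is
    floored at 0 and flagged, since negative concentrations are unphysical.
    """
    if not t_days > 0:
        raise ValidationError(f"exposure time must be > 0, got {t_days!r}")
    a, b = _coeffs(fit)
    value = a * math.log(t_days) + b
    if value < 0:
        return LC50Prediction(lc50_ugL=0.0, t_days=t_days, beyond_nlt=True)
    return LC50Prediction(lc50_ugL=value, t_days=t_days, beyond_nlt=False)


def predict_lt50(fit: "RLEFit | LinearFit", conc_ugL: float) -> RLEPrediction:
    """Median lethal time at ambient concentration `conc_ugL`.

    Inverts the line: LT50 = exp((c − b)/a).  At c = 0 this is exactly the
    normal life expectancy and the fraction of NLT is 1.
    """
    if conc_ugL < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc_ugL!r}")
    a, b = _coeffs(fit)
    if a >= 0:
        raise NoToxicityTrendError(f"slope must be negative, got a={a}")
    lt50 = math.exp((conc_ugL - b) / a)
    nlt = math.exp(-b / a)
    return RLEPrediction(concentration_ugL=conc_ugL, lt50_days=lt50,
                         fraction_of_nlt=lt50 / nlt)


def two_point_fit(lc50_ugL: float, t_days: float, nlt_days: float,
                  species: str = "", toxicant: str = "") -> RLEFit:
    """Fit the line through one acute endpoint and the NLT anchor.

    When only a single endpoint (typically the 96-hr LC50) is available,
    the line is drawn through (ln t, LC50) and (ln NLT, 0):

        a = −LC50 / (ln NLT − ln t),    b = −a · ln NLT.

    Both anchors are reproduced exactly; R² is 1 by construction.
    """
    if not lc50_ugL > 0:
        raise ValidationError(f"lc50 must be > 0, got {lc50_ugL!r}")
    if not t_days > 0:
        raise ValidationError(f"t_days must be > 0, got {t_days!r}")
    if not t_days < nlt_days:
        raise InconsistentInputsError(
            f"exposure time ({t_days} d) must be below the normal life "
            f"expectancy ({nlt_days} d)")
    ln_t, ln_nlt = math.log(t_days), math.log(nlt_days)
    a = -lc50_ugL / (ln_nlt - ln_t)
    b = -a * ln_nlt
    fit = LinearFit(slope_a=a, intercept_b=b, r_squared=1.0, n_points=2)
    return RLEFit(fit=fit, species=species, toxicant=toxicant, method="two_point")


def species_calculated_nlt(fits: Sequence[RLEFit],
                           r2_min: Optional[float] = None,
                           min_datasets: int = DEFAULT_MIN_DATASETS) -> NLTEstimate:
    """Species-level NLT: the arithmetic mean of per-dataset ln NLT values.

    Averaging is done on the log scale (mean of −b/a, then exponentiated).
    All fits must share one species.  Fits failing an optional R² filter are
    dropped first; fewer than `min_datasets` surviving datasets is an error,
    mirroring the ≥4-dataset rule for publishing a species value.
    """
    fits = list(fits)
    if not fits:
        raise InsufficientDatasetsError("no fits supplied")
    species = {f.species for f in fits}
    if len(species) > 1:
        raise ValidationError(f"fits span multiple species: {sorted(species)}")
    if r2_min is not None:
        fits = [f for f in fits if f.r_squared >= r2_min]
    if len(fits) < min_datasets:
        raise InsufficientDatasetsError(
            f"{species.pop()}: {len(fits)} usable dataset(s), need >= {min_datasets}")
    ln_values = [ln_nlt_from_fit(f).ln_nlt for f in fits]
    mean_ln = sum(ln_values) / len(ln_values)
    return NLTEstimate(ln_nlt=mean_ln, nlt_days=math.exp(mean_ln),
                       method="species_average", n_datasets=len(fits))


def internal_from_ambient(lc50_ugL: float, k_b: float) -> float:
    """Internal lethal concentration from the ambient one: ILC50 = K_B · LC50.

    K_B is the bioconcentration factor, the equilibrium ratio of body to
    water concentration.  Because the conversion is a fixed positive scale
    factor, a line fitted on the internal scale has the same x-intercept —
    the same ln NLT — as one fitted on the ambient scale.
    """
    if not k_b > 0:
        raise ValidationError(f"bioconcentration factor must be > 0, got {k_b!r}")
    if lc50_ugL < 0:
        raise ValidationError(f"lc50 must be >= 0, got {lc50_ugL!r}")
    return k_b * lc50_ugL


def compare_reported_vs_calculated(
        pairs: Sequence[Tuple[float, float]]) -> NLTComparison:
    """Through-origin regression of reported NLT on calculated NLT.

    `pairs` are (calculated_nlt_days, reported_nlt_days) per species.  The
    regression is run on both the day scale and the ln(day) scale and both
    fits are returned.
    """
    pairs = list(pairs)
    if len(pairs) < 2:
        raise InsufficientDataError(f"need >= 2 species pairs, got {len(pairs)}")
    for calc, rep in pairs:
        if not (calc > 0 and rep > 0):
            raise ValidationError(f"NLT values must be positive, got {(calc, rep)}")
    day = fit_through_origin(pairs)
    ln_pairs = [(math.log(c), math.log(r)) for c, r in pairs]
    ln = fit_through_origin(ln_pairs)
    return NLTComparison(day_scale=day, ln_scale=ln, n_species=len(pairs))
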