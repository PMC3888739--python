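"""Exception hierarchy for toxicity-model fitting and prediction."""


class RletoxError(Exception):
    """Base class for all package-specific errors."""


class UnitError(RletoxError, ValueError):
    """Unknown or inconsistent measurement unit."""


class ValidationError(RletoxError, ValueError):
    """Input value violates a documented precondition."""


class InsufficientDataError(RletoxError):
    """Fewer observations than the operation requires."""


class InsufficientDatasetsError(InsufficientDataError):
    """Fewer per-species datasets than the species-averaging rule requires."""


class DegenerateDesignError(RletoxError):
    """Regression design with no identifiable slope (e.g. all x identical)."""


class NoToxicityTrendError(RletoxError):
    """Fitted slope is non-negative: LC50 does not fall with exposure time,
    so life-expectancy extrapolation is undefined."""


class NegativeExtrapolationError(RletoxError):
    """Intercept not positive: the fitted line never reaches LC50 = 0 at a
    positive exposure time."""


class InconsistentInputsError(RletoxError, ValueError):
    """Mutually contradictory inputs (e.g. exposure time at or past the
    normal life expectancy in a two-point fit)."""


class DivergenceError(RletoxError):
    """Prediction requested at or below a model's asymptotic concentration,
    where the predicted time is infinite."""
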