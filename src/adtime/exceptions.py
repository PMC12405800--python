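"""Exception hierarchy for adtime."""


class AdtimeError(Exception):
    """Base class for all adtime errors."""


class ParameterError(AdtimeError, ValueError):
    """An argument violates a documented precondition."""


class InputDataError(AdtimeError, ValueError):
    """Input table or trajectory violates the expected schema/invariants."""


class UnidentifiableShiftError(AdtimeError):
    """The group curve has no curvature, so a time shift is unidentifiable.

    On a straight line g(t) = a*t the shifted prediction
    g(delta + t) - g(delta) = a*t for every delta.
    """


class ThresholdUndeterminedError(AdtimeError):
    """Gaussian-mixture positivity threshold could not be determined.

    Raised when the two fitted components collapse onto each other or the
    mixture density has no interior minimum between the component means
    (i.e. the sample looks unimodal).
    """


class CensoredValue(AdtimeError):
    """A biomarker value lies outside the integrated curve's range.

    Attributes
    ----------
    side : str
        ``"below"`` or ``"above"`` the curve range.
    """

    def __init__(self, value: float, side: str):
        self.value = value
        self.side = side
        super().__init__(f"value {value!r} is {side} the curve range")


class InsufficientDataError(AdtimeError):
    """Not enough usable data to carry out the requested fit."""


class ModelFitError(AdtimeError):
    """A statistical model failed to fit (separation, singularity, ...)."""
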