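"""Exception types shared across the analysis stages."""


class AlloLightError(Exception):
    """Base class for all package errors."""


class NonPositiveBaselineError(AlloLightError):
    """Raised when a fluorescence baseline (F0 or fitted reference) is <= 0."""


class NoDynamicRangeError(AlloLightError):
    """Raised when a titration has no usable response range (flat data)."""


class FitConvergenceError(AlloLightError):
    """Raised when a nonlinear fit fails to converge.

    The ``last_params`` attribute carries the last iterate, when available.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class InsufficientFamilyError(AlloLightError):
    """Raised when a titration family has too few modulator levels for a global fit."""


class SchemaError(AlloLightError):
    """Raised when an input table or config does not match the expected schema."""
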