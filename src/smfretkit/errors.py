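"""Exception types shared across the pipeline."""


class SmfretError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SmfretError, ValueError):
    """A parameter violates a documented precondition (negative rate, empty input, ...)."""


class BorderError(SmfretError):
    """A fit window would extend past the image border."""


class AmbiguousRegistrationError(SmfretError):
    """Channel registration could not find an unambiguous modal displacement."""


class EmptyInputError(SmfretError, ValueError):
    """An operation that needs at least one record received none."""


class ConvergenceError(SmfretError):
    """Iterative optimisation failed to converge.

    The best model found so far, when available, is attached as ``best_model``.
    """

    def __init__(self, message, best_model=None):
        super().__init__(message)
        self.best_model = best_model


class FitError(SmfretError):
    """A nonlinear fit failed on all starts; diagnostics in ``details``."""

    def __init__(self, message, details=None):
        super().__init__(message)
        self.details = details or {}


class AggregationError(SmfretError):
    """Guinier region has non-negative slope (aggregation or ill-posed data)."""


class DegenerateFitError(SmfretError, ValueError):
    """Input carries no information about the requested parameter (e.g. constant data)."""
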