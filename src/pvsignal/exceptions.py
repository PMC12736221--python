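"""Exception hierarchy for pvsignal."""


class PVSignalError(Exception):
    """Base class for all pvsignal errors."""


class FormatError(PVSignalError, ValueError):
    """A line-listing or mapping file violates the expected layout
    (missing mandatory column, unreadable header, bad delimiter)."""


class ValidationError(PVSignalError):
    """A field value, record, or configuration violates a domain invariant.

    Deliberately not a ValueError subclass so it survives pydantic's
    value-error wrapping when raised inside model validation.
    """


class UndefinedResultError(PVSignalError, ArithmeticError):
    """A statistic is undefined for the given contingency table
    (e.g. a zero denominator with the continuity correction disabled)."""


class ConvergenceError(PVSignalError, RuntimeError):
    """An iterative fit failed to converge from every start.

    Carries the best parameters found so the caller can inspect them.
    """

    def __init__(self, message, best=None, loglik=None):
        super().__init__(message)
        self.best = best
        self.loglik = loglik
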