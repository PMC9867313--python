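"""Exception hierarchy for the semfi package."""


class SemfiError(Exception):
    """Base class for all semfi errors."""


class SchemaError(SemfiError):
    """An input table is missing required columns or has unparseable cells."""


class ValidationError(SemfiError):
    """Rows of an input table violate the soil-sample invariants.

    Attributes
    ----------
    report : list of str
        One human-readable line per offending row/cell.
    """

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = list(report or [])


class DegenerateColumnError(SemfiError):
    """A column required to have positive variance is constant."""


class SingularMatrixError(SemfiError):
    """A correlation/covariance matrix is singular or not positive definite."""


class NotConvergedError(SemfiError):
    """The ML optimizer failed to reach a stationary point.

    Attributes
    ----------
    grad_norm : float
        Gradient norm at the last iterate.
    """

    def __init__(self, message, grad_norm=float("nan")):
        super().__init__(message)
        self.grad_norm = grad_norm


class ScoringDomainError(SemfiError):
    """A measured value or reference mean is outside the scoring domain."""


class IndicatorMismatchError(SemfiError):
    """Score columns and weight entries do not cover the same indicators."""
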