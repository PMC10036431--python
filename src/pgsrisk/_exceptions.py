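"""Exception hierarchy.

Every validation or numerical failure raised by this package derives from
:class:`PgsRiskError`, so callers can catch one type at pipeline level.
"""


class PgsRiskError(Exception):
    """Base class for all pgsrisk errors."""


class InvalidConfigError(PgsRiskError, ValueError):
    """A configuration object violates its invariants."""


class FormatError(PgsRiskError, ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(PgsRiskError, ValueError):
    """An in-memory container violates its invariants."""


class EmptyIntersectionError(PgsRiskError):
    """Harmonization matched zero variants."""


class DegenerateScoreError(PgsRiskError):
    """A polygenic score has zero variance and cannot be standardized."""


class CollinearityError(PgsRiskError):
    """A covariate matrix is rank deficient."""


class FoldDegeneracyError(PgsRiskError):
    """A cross-validation fold contains no events; reduce the fold count."""


class ConvergenceError(PgsRiskError):
    """Newton–Raphson failed to converge; carries the final gradient norm."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class SeparationError(ConvergenceError):
    """Monotone partial likelihood (perfect separation): |beta| diverges."""


class ExtrapolationError(PgsRiskError):
    """Prediction horizon lies beyond the last observed event time."""


class DegenerateGroupingError(PgsRiskError):
    """A requested grouping (decile, bin) is empty or ill-defined."""


class AlignmentError(PgsRiskError):
    """Two objects that must share a sample set do not."""
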