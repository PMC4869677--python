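"""Exception hierarchy for hprglm.

All package-specific errors derive from :class:`HprglmError` so callers can
catch everything from this package with one clause.  Argument-validation
errors additionally derive from :class:`ValueError` and configuration errors
from :class:`KeyError`-free plain ``HprglmError`` subclasses, so idiomatic
``except ValueError`` handling keeps working.
"""


class HprglmError(Exception):
    """Base class for all hprglm errors."""


class ArgumentError(HprglmError, ValueError):
    """An operation was called with invalid arguments."""


class ConfigurationError(HprglmError, ValueError):
    """An unknown design, policy, or configuration key was requested."""


class DomainError(HprglmError, ValueError):
    """Input values are outside the physically meaningful domain."""


class NoQRSDetectedError(HprglmError, RuntimeError):
    """The QRS detector found no heartbeat in the record."""


class DegenerateBasisError(HprglmError, ValueError):
    """Gram-Schmidt orthogonalization encountered a linearly dependent shape."""


class EstimationError(HprglmError, RuntimeError):
    """GLM inversion failed (e.g. rank-deficient design matrix)."""


class SelectionError(HprglmError, RuntimeError):
    """Stepwise response-function selection could not retain any candidate."""


class ScoringError(HprglmError, RuntimeError):
    """Peak scoring failed (e.g. NaN inside a scoring window)."""
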