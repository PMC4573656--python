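"""Exception hierarchy for allocov.

All errors raised on bad user input derive from :class:`AllocovError` so
callers (and the CLI) can catch one base class.
"""


class AllocovError(Exception):
    """Base class for all allocov errors."""


class InputError(AllocovError, ValueError):
    """Invalid user input (missing height, non-positive DBH, bad schema ...)."""


class SingularDesignError(AllocovError):
    """Gradient/design matrix is rank deficient; carries a condition diagnostic."""

    def __init__(self, message: str, condition_number: float | None = None):
        super().__init__(message)
        self.condition_number = condition_number


class DegenerateSampleError(AllocovError):
    """A sample with zero prediction variance (all trees identical)."""


class NoSolutionError(AllocovError):
    """A parameter solve has no real-valued solution (gamma nu, df too small)."""


class UnsupportedCaseError(AllocovError):
    """A case the method deliberately refuses (e.g. shared-equation aggregation)."""


class LookupError_(AllocovError, KeyError):
    """Unknown registry name; message lists available names."""


class ConvergenceError(AllocovError):
    """Too many replicate failures in an iterative recovery."""
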