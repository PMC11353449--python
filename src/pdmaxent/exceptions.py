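"""Exception types raised across the package."""


class PdMaxentError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PdMaxentError, ValueError):
    """Raised when numeric input is malformed (non-finite, wrong shape, ...)."""


class InvalidPriorError(PdMaxentError, ValueError):
    """Raised when a prior distribution is not strictly positive or unnormalized."""


class DegeneratePathError(PdMaxentError, ValueError):
    """Raised when the path start hyperparameter is zero (prior already optimal)."""


class UnsupportedRegularizerError(PdMaxentError, ValueError):
    """Raised when a solver is called with a regularizer it cannot handle."""


class ConvergenceError(PdMaxentError, RuntimeError):
    """Raised when an iterative routine fails to converge or diverges."""
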