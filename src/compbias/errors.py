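"""Exception hierarchy for compbias."""


class CompbiasError(Exception):
    """Base class for all package-specific errors."""


class EmptyInputError(CompbiasError):
    """Raised when an operation receives no usable records/observations."""


class FormatError(CompbiasError, ValueError):
    """Raised when an input file violates its declared format."""


class ContractViolation(CompbiasError, ValueError):
    """Raised when a caller violates a documented precondition."""


class DegenerateModelError(CompbiasError):
    """Raised when a model cannot be estimated (constant covariate, single
    group, fewer observations than parameters, ...)."""


class InfiniteDivergenceError(CompbiasError):
    """Raised when a Kullback-Leibler term has positive observed mass on an
    event of zero expected probability."""
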