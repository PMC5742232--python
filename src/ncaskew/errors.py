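"""Exception types shared across the package."""


class NCAError(Exception):
    """Base class for all package-specific errors."""


class UndefinedScopeError(NCAError):
    """Raised when the data span a zero-area scope (constant x or constant y)."""


class UndefinedSkewnessError(NCAError):
    """Raised when skewness is requested for a constant sample."""


class InvalidShapeError(NCAError):
    """Raised for non-positive beta-distribution shape parameters."""


class BoundaryEffectError(NCAError):
    """Raised when logit() is evaluated at 0 or 1; callers decide exclusion policy."""


class FlatCeilingError(NCAError):
    """Raised when a bottleneck table is requested for a zero-slope ceiling line."""


class UnfittableModelError(NCAError):
    """Raised when a meta-regression has too few usable records or a collinear design."""


class InputDataError(NCAError):
    """Raised for unusable input files (missing columns, too few numeric rows)."""
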