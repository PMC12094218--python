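"""Exception types shared across the package."""


class CosinorError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CosinorError, ValueError):
    """An argument is outside its documented domain."""


class RankError(CosinorError, ValueError):
    """A design matrix is numerically rank-deficient.

    Raised e.g. when fewer than three distinct times modulo the period
    are available, so the cosine/sine columns are collinear with the
    intercept and amplitude/phase are unidentifiable.
    """


class InsufficientDataError(CosinorError, ValueError):
    """Too few observations for a residual degree of freedom."""


class NotAchievableError(CosinorError, ValueError):
    """A sample-size target cannot be met within the configured cap."""


class DesignFileError(CosinorError, ValueError):
    """A design or measurement CSV could not be parsed."""
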