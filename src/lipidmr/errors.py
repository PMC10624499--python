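"""Exception hierarchy for the MR pipeline.

Every error raised on a user-facing path derives from :class:`LipidMRError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class LipidMRError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LipidMRError):
    """A run/dialect/simulation configuration is invalid or incomplete."""


class ValidationError(LipidMRError):
    """Input data violate a documented invariant."""


class FormatError(LipidMRError):
    """A file could not be parsed in the declared dialect."""


class NoSharedVariantsError(LipidMRError):
    """Exposure and outcome datasets share no variant IDs."""


class MissingVariantError(LipidMRError):
    """A required variant is absent from a companion resource (e.g. LD matrix)."""


class EstimationError(LipidMRError):
    """An estimator's preconditions are not met."""


class UndefinedRatioError(EstimationError):
    """Wald ratio with a zero variant-exposure effect."""


class InsufficientInstrumentsError(EstimationError):
    """Too few instruments for the requested method."""


class CollinearityError(EstimationError):
    """Degenerate design: no variation in, or rank-deficient, exposure effects."""


class ConditioningError(EstimationError):
    """LD-derived covariance is numerically singular after repair."""
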