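"""Exception hierarchy shared across the package.

Exit-code classes used by the CLI: ConfigError -> 2, data/format errors -> 3,
anything else -> 4.
"""


class AffectError(Exception):
    """Base class for all package errors."""


class ConfigError(AffectError):
    """Invalid configuration or hyperparameter value."""


class DataFormatError(AffectError):
    """Malformed input table (missing column, bad value, schema violation)."""


class EmptyInputError(DataFormatError):
    """No usable rows remain after filtering, or an empty input was given."""


class InsufficientCoverageError(DataFormatError):
    """Frame series does not cover the requested time window."""


class DomainError(AffectError):
    """Argument outside the mathematical domain of an operation."""


class DegenerateSampleError(AffectError):
    """A statistic is undefined for the sample (zero variance, too few points)."""


class NotFittedError(AffectError):
    """Prediction requested from an estimator that has not been trained."""
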