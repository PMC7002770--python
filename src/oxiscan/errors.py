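"""Exception hierarchy.

Exit-code mapping used by the CLI: ValidationError family -> 2,
FitError family -> 3, anything else -> 1.
"""


class OxiscanError(Exception):
    """Base class for all package errors."""


class ValidationError(OxiscanError):
    """Invalid inputs: bad config fields, malformed tables, bad p-values."""


class ConfigError(ValidationError):
    """A simulation or run configuration field is invalid."""


class SchemaError(ValidationError):
    """A table file is missing required columns or has duplicate keys."""


class SignatureCoverageError(ValidationError):
    """No signature gene overlaps the expression matrix."""


class CohortSizeError(ValidationError):
    """Too few samples (or groups) for the requested operation."""


class DegenerateDataError(ValidationError):
    """Zero-variance / constant input where spread is required."""


class JoinError(ValidationError):
    """Sample-identifier sets do not overlap."""


class FitError(OxiscanError):
    """Model fitting failed (non-convergence, degenerate likelihood)."""


class RankError(FitError):
    """Design matrix is rank deficient (collinear terms)."""


class NestingError(FitError):
    """Models passed to a likelihood-ratio comparison are not nested/comparable."""
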