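"""Exception hierarchy shared across the package.

All errors raised deliberately by the library derive from
:class:`NarrativeEncodingError`, so callers can distinguish validated
domain failures from programming errors.
"""


class NarrativeEncodingError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NarrativeEncodingError, ValueError):
    """A parameter violates its documented domain (e.g. |r| >= 1)."""


class MalformedInputError(NarrativeEncodingError, ValueError):
    """Input data violates a structural contract (non-monotone time, non-binary labels...)."""


class ShapeMismatchError(NarrativeEncodingError, ValueError):
    """Two objects that must share a grid/shape do not."""


class EmptyCohortError(NarrativeEncodingError, ValueError):
    """Every participant was excluded, or no valid data remains."""


class InsufficientDataError(NarrativeEncodingError, ValueError):
    """Too few participants/timepoints for the requested statistic."""


class UndefinedStatisticError(NarrativeEncodingError, ValueError):
    """A statistic is undefined for the given input (constant series, zero variance)."""


class EstimationError(NarrativeEncodingError, ValueError):
    """Model estimation failed (rank deficiency, non-convergent quadrature)."""


class DegenerateMaskError(NarrativeEncodingError, ValueError):
    """A mask or label set is empty where a nonempty one is required."""


class FormatError(NarrativeEncodingError, ValueError):
    """On-disk data failed validation at load time."""
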