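"""Exception hierarchy for arcequate.

All package errors derive from :class:`ArcEquateError` so callers can
catch one base class at pipeline boundaries.
"""


class ArcEquateError(Exception):
    """Base class for all arcequate errors."""


class SchemaError(ArcEquateError):
    """A delimited-text file does not carry the expected columns."""


class CohortValidationError(ArcEquateError):
    """A subject record violates a score or demographic invariant."""


class AnchorError(ArcEquateError):
    """Anchor points violate the strict ordering x1 < x2 < x3 or bounds."""


class DegenerateAnchorError(AnchorError):
    """The nadir and zenith share the same source score (x1 == x3)."""


class InsufficientDataError(ArcEquateError):
    """Too few distinct source scores to extract three anchor points."""


class OutOfArcDomainError(ArcEquateError):
    """The arc formula was evaluated where r^2 - (x - xc)^2 < 0."""


class ConversionLookupError(ArcEquateError):
    """A source score falls outside the conversion table's range."""


class UndefinedCorrelationError(ArcEquateError):
    """Correlation requested on a constant or too-short vector."""
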