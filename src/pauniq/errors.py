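"""Exception hierarchy for pauniq.

All pauniq-raised errors derive from :class:`PauniqError` so callers can
catch the package's failures with a single except clause while still
distinguishing schema problems from numerical ones.
"""


class PauniqError(Exception):
    """Base class for all errors raised by pauniq."""


class SchemaError(PauniqError):
    """An input file is missing required columns or fields."""


class ValidationError(PauniqError):
    """Input data violate a structural invariant (duplicate ids, empty sets, ...)."""


class DomainError(PauniqError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class GeometryError(PauniqError):
    """A geometry is invalid, degenerate, or missing where required."""


class JoinError(PauniqError, KeyError):
    """An identifier cannot be resolved against the table it refers to."""


class FittingError(PauniqError):
    """Model fitting failed or the design is degenerate."""


class PlacementError(PauniqError):
    """A synthetic protected area could not be placed after bounded retries."""


class UndefinedDissimilarityError(PauniqError):
    """Dissimilarity requested between two empty (all-zero) assemblages."""
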