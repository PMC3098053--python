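"""Exception hierarchy for ssevec."""


class SsevecError(Exception):
    """Base class for all ssevec errors."""


class ParseError(SsevecError):
    """A structure or representation file could not be parsed."""


class ChainNotFoundError(SsevecError):
    """A requested chain is absent from the structure."""


class ValidationError(SsevecError):
    """An input violates a documented precondition or invariant."""


class FormatError(SsevecError):
    """A representation record is malformed; the message names the field."""


class DegenerateGeometryError(SsevecError):
    """Geometry too degenerate to define an axis (e.g. coincident points)."""


class EmptyRepresentationError(SsevecError):
    """No secondary-structure elements survive reduction."""


class UndefinedStatisticsError(SsevecError):
    """Rotational statistics are undefined (no same-type pair, or zero spread)."""


class EmptyDatabaseError(SsevecError):
    """A database build produced no valid entries."""
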