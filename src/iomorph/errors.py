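"""Exception hierarchy for the iomorph pipeline.

Every error raised by the library derives from :class:`IomorphError`, so
callers (and the CLI) can catch pipeline failures with a single handler
while still distinguishing schema problems from geometric degeneracies.
"""


class IomorphError(Exception):
    """Base class for all iomorph errors."""


class FormatError(IomorphError):
    """A file could not be parsed in the expected format."""


class SchemaError(IomorphError):
    """Structured input violates its schema (e.g. wrong landmark roles)."""


class ValidationError(IomorphError):
    """A domain object violates one of its invariants."""


class MetadataError(IomorphError):
    """Required metadata (e.g. gauge length) is absent or invalid."""


class OrderingError(IomorphError):
    """A series that must be monotone is not."""


class DegeneracyError(IomorphError):
    """Geometry is too degenerate for the requested measurement."""


class EmptyResultError(IomorphError):
    """An operation produced no data (empty clip, empty slab, empty pool)."""


class ConfigurationError(IomorphError):
    """A parameter set is internally inconsistent."""


class InsufficientLoadError(IomorphError):
    """A tensile curve never reaches the preload threshold."""


class InsufficientDataError(IomorphError):
    """Too few samples for the requested analysis."""
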