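"""Exception hierarchy shared across the platform."""


class SSTError(Exception):
    """Base class for all platform errors."""


class FormatError(SSTError):
    """A document could not be parsed in the expected format."""


class ModeError(SSTError):
    """Acquisition mode mismatch, e.g. centroid data where profile is required."""


class EmptyInputError(SSTError):
    """An operation received an empty acquisition or series."""


class ConfigurationError(SSTError):
    """Inconsistent or impossible configuration values."""


class SchemaError(SSTError):
    """A feature vector, registry or flag set does not match the active schema."""


class RangeError(SSTError):
    """A requested m/z window lies outside the spectrum range."""


class InsufficientDataError(SSTError):
    """Not enough runs/points to carry out a statistical operation."""


class ConflictError(SSTError):
    """Attempt to overwrite an existing run without explicit permission."""


class StoreError(SSTError):
    """The run store is missing or not initialized."""


class SelectionError(SSTError):
    """Scan selection failed (flat chronogram or apex too close to the end)."""
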