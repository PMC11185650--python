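"""Exception hierarchy shared by every pixikit module."""


class PixikitError(Exception):
    """Base class for all pixikit errors."""


class ValidationError(PixikitError):
    """An input violates a documented invariant or precondition."""


class ConflictError(PixikitError):
    """An identifier or name collides with an existing entity."""


class EmptyAnnotationError(ValidationError):
    """A selection or rasterization produced no foreground pixels."""


class UnsupportedFormatError(PixikitError):
    """A file is in a format (or variant) the reader does not handle."""


class SchemaVersionError(PixikitError):
    """A project archive was written with an incompatible schema version."""
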