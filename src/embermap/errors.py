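"""Exception hierarchy shared across the pipeline."""


class EmbermapError(Exception):
    """Base class for all package errors."""


class SchemaError(EmbermapError):
    """An input table or file violates its declared schema."""


class ParseError(EmbermapError):
    """A file could not be parsed in its declared format."""


class InvalidArgumentError(EmbermapError, ValueError):
    """An argument is outside its documented domain."""


class IncompleteStrataError(EmbermapError):
    """A stratum required by the standard population is missing."""
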