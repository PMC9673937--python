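"""Exception hierarchy."""


class AminorError(Exception):
    """Base class for all package errors."""


class ParseError(AminorError):
    """A file could not be parsed; message names the offending line/pointer."""


class SchemaError(ParseError):
    """A JSON document violates the graph schema."""


class ValidationError(AminorError):
    """Data parsed fine but violates a model invariant."""


class GeometryError(AminorError):
    """Degenerate or missing 3D coordinates."""
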