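"""Exception hierarchy shared across the package."""


class RadrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RadrError):
    """A file does not conform to its declared format (GCT, GMT, TSV...)."""


class SchemaError(RadrError):
    """A table is missing required columns or has unparseable values."""


class ValidationError(RadrError):
    """A domain object violates one of its invariants."""
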