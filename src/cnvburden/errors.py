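"""Exception hierarchy shared across the pipeline."""


class CnvBurdenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(CnvBurdenError):
    """A line or field in an input file could not be parsed."""


class SchemaError(CnvBurdenError):
    """An input table is missing required columns."""


class ValidationError(CnvBurdenError):
    """Parsed input violates a domain invariant."""
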