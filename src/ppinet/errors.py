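"""Exception hierarchy shared across the package."""


class PpinetError(Exception):
    """Base class for all package errors."""


class ParseError(PpinetError):
    """A file could not be parsed (malformed line, missing column, ...)."""


class ValidationError(PpinetError):
    """Parsed or supplied data violates a documented invariant."""


class ConfigurationError(PpinetError):
    """A configuration value is missing, unknown or out of range."""
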