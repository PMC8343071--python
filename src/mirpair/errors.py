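"""Exception types shared across the package."""


class MirpairError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MirpairError):
    """An invalid configuration value; the message names the offending field."""


class ParseError(MirpairError):
    """A malformed input table; the message carries a line number where possible."""


class SchemaError(MirpairError):
    """A serialized model file missing required fields or holding bad types."""
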