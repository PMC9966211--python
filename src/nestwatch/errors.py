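"""Exception types shared across the pipeline."""


class NestwatchError(Exception):
    """Base class for all package errors."""


class ParseError(NestwatchError, ValueError):
    """A file could not be parsed in the declared dialect.

    The message names the offending line or entry.
    """


class ValidationError(NestwatchError, ValueError):
    """An object violates a domain invariant (e.g. non-monotone timestamps)."""


class ConfigurationError(NestwatchError, ValueError):
    """A configuration value is outside the supported set."""


class InsufficientDataError(NestwatchError, ValueError):
    """A series is too short for the requested operation."""
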