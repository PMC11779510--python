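"""Exception hierarchy used across the pipeline."""


class AristopError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AristopError, ValueError):
    """A configuration value is inconsistent or out of range."""


class UsageError(AristopError, ValueError):
    """An operation was called on inputs it is not defined for."""


class UndefinedInputError(AristopError, ValueError):
    """A summary statistic was requested on an empty selection."""


class DegenerateInputError(AristopError, ValueError):
    """A signal operation received input it cannot act on (too short,
    zero variance, insufficient pre-event samples)."""


class SessionLoadError(AristopError, ValueError):
    """A session bundle on disk is incomplete or malformed."""
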