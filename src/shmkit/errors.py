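"""Exception hierarchy shared across shmkit modules."""


class ShmkitError(Exception):
    """Base class for all shmkit-specific errors."""


class AlphabetError(ShmkitError, ValueError):
    """A sequence contains characters outside the permitted alphabet."""


class MotifDomainError(ShmkitError, ValueError):
    """A motif argument is not a member of the expected motif family."""


class DataError(ShmkitError, ValueError):
    """Structurally invalid input data (length mismatch, bad record, ...)."""


class ConfigError(ShmkitError, ValueError):
    """Invalid configuration (impossible geometry, bad threshold, ...)."""
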