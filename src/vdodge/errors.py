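"""Exception hierarchy shared across the package."""


class VdodgeError(Exception):
    """Base class for all package errors."""


class ValidationError(VdodgeError, ValueError):
    """Invalid value supplied by the caller (exit code 2 at the CLI)."""


class ConfigurationError(VdodgeError, KeyError):
    """A required configuration entry (segment, length, column) is missing."""


class GenerationError(VdodgeError, RuntimeError):
    """The synthetic generator could not realize a requested condition cell."""


class DegenerateTrialError(VdodgeError, ValueError):
    """A recording carries no usable movement (e.g. all-zero speed)."""
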