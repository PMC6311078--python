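"""Exception hierarchy shared across the package."""


class TridcaError(Exception):
    """Base class for all package errors."""


class InvalidMSAError(TridcaError):
    """The alignment is malformed (ragged, empty, or illegal characters)."""


class EmptyMSAError(InvalidMSAError):
    """No sequences survive preprocessing."""


class ConfigurationError(TridcaError):
    """A parameter or input file violates its contract."""


class InversionError(TridcaError):
    """The covariance matrix could not be inverted."""


class MemoryBudgetError(TridcaError):
    """A requested tensor would exceed the configured memory cap."""
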