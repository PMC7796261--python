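"""Exception hierarchy.

All argument-contract violations raise :class:`ArgumentError` (a ValueError)
so callers can distinguish bad inputs from numerical or data failures.
"""


class EcgidError(Exception):
    """Base class for all package errors."""


class ArgumentError(EcgidError, ValueError):
    """A precondition on an argument was violated."""


class DataError(EcgidError):
    """Input data is structurally invalid (e.g. a missing peak annotation)."""


class InsufficientDataError(DataError):
    """Not enough samples/peaks to run the operation."""


class NumericalError(EcgidError):
    """A numerically degenerate situation (e.g. singular covariance)."""


class ParseError(EcgidError):
    """A file could not be parsed; message carries line/record context."""


class ConfigError(EcgidError):
    """Pipeline configuration is inconsistent with the supplied data."""
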