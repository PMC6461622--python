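"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so batch callers can tell a
misconfigured run from corrupt data or a numerical failure.
"""


class IscoctaError(Exception):
    """Base class for all package errors."""


class ConfigError(IscoctaError, ValueError):
    """Invalid configuration: bad protocol fields, out-of-range parameters."""


class DataError(IscoctaError, ValueError):
    """Input data inconsistent with its declared geometry or scale."""


class NumericalError(IscoctaError, ArithmeticError):
    """A computation produced an undefined or non-finite result."""
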