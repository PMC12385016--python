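"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors exit 2, data
errors exit 3, numeric failures exit 4.
"""


class GradiomicsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GradiomicsError):
    """Invalid configuration value (bad threshold, fraction, grid, ...)."""


class DataError(GradiomicsError):
    """Unreadable, inconsistent or degenerate input data."""


class NumericError(GradiomicsError):
    """Non-finite values or numerically impossible requests."""


class AdapterError(GradiomicsError):
    """A backbone adapter was used outside its declared capabilities."""


class PairingError(DataError):
    """Two per-sample objects that must refer to the same sample do not."""


class NotFittedError(GradiomicsError):
    """A model was queried before ``fit`` was called."""
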