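"""Exception hierarchy shared across the package."""


class NetpolError(Exception):
    """Base class for package errors."""


class ConfigError(NetpolError):
    """Invalid configuration, parameters, or ranges."""


class DataError(NetpolError):
    """Invalid or inconsistent input data."""


class DegenerateInputError(DataError):
    """Statistically degenerate input (e.g. zero variance where variance is required)."""
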