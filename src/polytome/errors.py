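"""Exception types shared across the package."""


class PolytomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PolytomeError, ValueError):
    """An input configuration is invalid or infeasible."""


class DataError(PolytomeError, ValueError):
    """An input table, sequence or annotation violates its contract."""
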