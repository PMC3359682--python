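"""Exception hierarchy shared across the package.

ConfigurationError maps to CLI exit code 2, NumericalError to exit code 3.
"""


class EchoThermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EchoThermError, ValueError):
    """Invalid parameters or inconsistent configuration (CLI exit code 2)."""


class MemoryGuardError(ConfigurationError):
    """A requested register extension exceeds the configured sample cap."""


class NumericalError(EchoThermError, RuntimeError):
    """A numerical failure during fitting or peak search (CLI exit code 3)."""


class PeakLostError(NumericalError):
    """The tracked spectral peak could not be located in the search band."""
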