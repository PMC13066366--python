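"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and
subclasses) -> 3, NumericalError -> 4.
"""


class AgballocError(Exception):
    """Base class for package errors."""


class ConfigError(AgballocError):
    """Invalid configuration (bad endmembers, cover outside (0,1), ...)."""


class DataError(AgballocError):
    """Invalid or insufficient data."""


class AlignmentError(DataError):
    """Grids or cubes do not share shape / year coordinates."""


class SamplingError(DataError):
    """Requested more survey plots than available pixel-years."""


class NumericalError(AgballocError):
    """Degenerate or singular numerical problem."""
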