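"""Exception and warning hierarchy.

Exit-code mapping used by the CLI:
input/validation errors -> 2, convergence failures -> 3, config/parse errors -> 4.
"""


class MRTEUDError(Exception):
    """Base class for all package errors."""


class InputError(MRTEUDError, ValueError):
    """Invalid numerical or structural input (bad histogram, bad dose map, ...)."""


class ConfigError(MRTEUDError, ValueError):
    """Malformed configuration, tissue table or constraint file."""


class ConvergenceError(MRTEUDError, RuntimeError):
    """An iterative solve (e.g. D98% normalization) failed to converge."""


class GeometryError(InputError):
    """Empty structures, rays missing the grid, incongruent grids."""


class UndefinedRatioError(InputError):
    """PVDR requested with a zero valley dose."""


class SurvivalUnderflowWarning(RuntimeWarning):
    """Survival fraction underflowed to zero in double precision."""
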