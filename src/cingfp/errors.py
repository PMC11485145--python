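"""Exception hierarchy.

``ValidationError`` and its subclasses signal bad user input or
configuration (CLI exit code 2); every other :class:`CingfpError`
signals a runtime failure (exit code 1).
"""


class CingfpError(Exception):
    """Base class for all package errors."""


class ValidationError(CingfpError, ValueError):
    """Invalid input values, shapes, or configuration."""


class DimensionalityError(ValidationError):
    """Image has the wrong number of dimensions."""


class ConsistencyError(ValidationError):
    """Mismatch between related artifacts (grid vs. table, manifest vs. report)."""


class ConfigError(ValidationError):
    """Invalid pipeline or generator configuration."""


class CapacityError(ValidationError):
    """Request exceeds what the data can support (e.g. more seeds than ROI voxels)."""


class PlacementError(CingfpError):
    """Phantom regions cannot be placed without overlap at the requested grid size."""


class FrequencyError(ValidationError):
    """Filter band incompatible with the sampling rate."""


class InsufficientDataError(ValidationError):
    """Too few observations to compute the requested statistic."""


class ConvergenceError(CingfpError):
    """Iterative algorithm failed to converge."""

    def __init__(self, message: str, n_iter: int | None = None):
        super().__init__(message)
        self.n_iter = n_iter


class DegenerateDataError(CingfpError):
    """Data degenerate for the requested model (e.g. zero error variance)."""


class MappingError(ValidationError):
    """Homolog/target name mapping does not resolve."""
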