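"""Exception hierarchy shared across the package."""


class MwablateError(Exception):
    """Base class for all package errors."""


class GridMismatchError(MwablateError):
    """Two fields that must share a voxel grid do not."""


class GeometryError(MwablateError):
    """A geometric construction falls outside its allowed domain."""


class StabilityError(MwablateError):
    """An explicit time step violates the CFL-like stability bound."""


class CalibrationError(MwablateError):
    """Source calibration failed to converge or is underdetermined."""


class TableRangeError(MwablateError):
    """Power/duration query outside the manufacturer table range."""


class UndefinedMetricError(MwablateError):
    """A metric is mathematically undefined for the given inputs."""


class ConvergenceError(MwablateError):
    """An iterative construction did not reach its target."""
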