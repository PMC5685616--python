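"""Exception hierarchy shared by every module."""


class SdmError(Exception):
    """Base class for all package errors."""


class FormatError(SdmError):
    """Unreadable or unsupported file format."""


class AlignmentError(SdmError):
    """Two grids that must share shape/origin/cell size/CRS do not."""


class GeometryError(SdmError):
    """Degenerate or invalid polygon geometry."""


class ConfigError(SdmError):
    """Invalid configuration (unknown key, impossible value)."""


class SimulationError(SdmError):
    """Synthetic-data request that cannot be satisfied."""


class PlacementError(SimulationError):
    """Protected areas could not be placed without overlap."""


class EvaluationError(SdmError):
    """Model evaluation on empty or degenerate inputs."""


class SamplingError(SdmError):
    """Random sample larger than the available population."""
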