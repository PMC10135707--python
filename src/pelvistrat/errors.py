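"""Exception types shared across the pipeline stages."""


class PelvistratError(Exception):
    """Base class for all package-specific errors."""


class SizingError(PelvistratError):
    """Requested phantom geometry does not fit on the voxel grid."""


class MeasurementError(PelvistratError):
    """A geometric measurement is undefined for the given volume."""


class ConfigurationError(PelvistratError):
    """Inconsistent or degenerate configuration values."""


class FormatError(PelvistratError):
    """A volume file could not be parsed."""


class MetadataError(PelvistratError):
    """Required image metadata (e.g. voxel spacing) is missing."""


class StratificationError(PelvistratError):
    """A class is absent from the labels, so stratified splitting fails."""


class TrainingDivergedError(PelvistratError):
    """The training loss became non-finite."""


class ShapeError(PelvistratError):
    """A tensor does not have the spatial shape an operator requires."""
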