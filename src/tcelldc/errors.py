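"""Exception hierarchy shared across the package."""


class TcellDcError(Exception):
    """Base class for all package-specific errors."""


class FieldSizingError(TcellDcError):
    """Simulated field too small to place the requested cells."""


class StackParseError(TcellDcError):
    """A stack file on disk could not be parsed."""


class TrackSchemaError(TcellDcError):
    """A track CSV is missing a required column."""


class CropSizingError(TcellDcError):
    """Field smaller than the requested crop window."""


class FrameExclusionError(TcellDcError):
    """Cell has too few frames for the requested sampling mode."""


class StratificationError(TcellDcError):
    """Dataset split impossible because a class is absent."""


class InputShapeError(TcellDcError):
    """Model input does not match the declared input shape."""


class LayerNotFoundError(TcellDcError):
    """Requested layer name does not exist in the model."""


class AlignmentError(TcellDcError):
    """Two per-cell collections do not describe the same cells."""


class TrainingDivergedError(TcellDcError):
    """Loss became non-finite during training."""
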