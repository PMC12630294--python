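"""Exception hierarchy shared across the pipeline stages."""


class FemkitError(Exception):
    """Base class for all femkit errors."""


class ConfigError(FemkitError):
    """Invalid configuration or parameter values."""


class GazeFormatError(FemkitError):
    """Input file does not conform to the expected gaze dialect."""


class GazeDataError(FemkitError):
    """Structurally valid input whose content violates a data invariant."""


class CalibrationError(GazeDataError):
    """Zero-point calibration could not be performed."""


class SegmentationError(GazeDataError):
    """Trial manifest does not fit the recording."""


class DetectionError(GazeDataError):
    """Event detection could not run on the given segment."""


class DegenerateSignalError(DetectionError):
    """Velocity noise estimate collapsed (constant or pathological input)."""


class DegenerateGeometryError(GazeDataError):
    """Point set too small or collinear for the requested statistic."""
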