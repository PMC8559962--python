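"""Exception types shared across the pipeline."""


class ChromotraceError(Exception):
    """Base class for all package errors."""


class InvalidPartitionError(ChromotraceError):
    """A cluster partition does not cover the centromere/telomere units exactly once."""


class InvalidClusterError(ChromotraceError):
    """A cluster composition is empty or references unknown units."""


class SegmentationError(ChromotraceError):
    """Nuclear segmentation produced no usable foreground."""


class CalibrationError(ChromotraceError):
    """A movie lacks required physical calibration metadata."""

    def __init__(self, field: str, message: str | None = None):
        self.field = field
        super().__init__(message or f"missing calibration field: {field}")


class DependencyError(ChromotraceError):
    """A pipeline stage was requested before its upstream artifact exists."""


class DetectionError(ChromotraceError):
    """Spot detection was configured below the resolvable scale or on an invalid region."""
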