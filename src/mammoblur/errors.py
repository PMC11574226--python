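"""Exception hierarchy for the blur-detection pipeline."""


class MammoblurError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MammoblurError, ValueError):
    """Input file cannot be parsed or has an unsupported layout."""


class MetadataError(MammoblurError, ValueError):
    """Required acquisition metadata is missing or ambiguous."""


class ShapeError(MammoblurError, ValueError):
    """Array input has the wrong shape for the requested operation."""


class PlacementError(MammoblurError, ValueError):
    """A region of interest violates its placement constraints."""


class SegmentationError(MammoblurError, RuntimeError):
    """Breast segmentation failed (e.g. no foreground found)."""


class ConfigurationError(MammoblurError, ValueError):
    """A configuration value is out of range or inconsistent."""


class IntegrityError(MammoblurError, RuntimeError):
    """A dataset integrity constraint (e.g. patient leakage) is violated."""


class UndefinedMetricError(MammoblurError, ValueError):
    """A statistic is undefined for the given input (e.g. one class only)."""


class DegenerateImageWarning(UserWarning):
    """Raised when an image is degenerate (e.g. constant intensity)."""
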