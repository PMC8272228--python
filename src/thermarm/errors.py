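"""Exception hierarchy for the pipeline."""


class ThermArmError(Exception):
    """Base class for all pipeline errors."""


class InvalidProtocolError(ThermArmError):
    """A training protocol violates its invariants."""


class ConfigError(ThermArmError):
    """A configuration value is invalid."""


class FrameValidationError(ThermArmError):
    """A temperature frame fails plausibility validation."""


class ManifestError(ThermArmError):
    """A session manifest is inconsistent or incomplete."""


class DegenerateHistogramError(ThermArmError):
    """A frame has too few distinct values for histogram thresholding."""


class SegmentationError(ThermArmError):
    """Arm segmentation produced no usable foreground."""


class ResolutionError(ThermArmError):
    """A region of interest is too small for the requested grid."""


class TimelineError(ThermArmError):
    """A recording does not cover the protocol's frame-selection times."""


class RegionUndefinedError(ThermArmError):
    """A muscle region has no non-missing heat-map cells."""
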