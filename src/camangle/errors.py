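"""Typed exceptions raised by the measurement pipeline.

Every anticipated failure mode (bad input file, degenerate anatomy,
non-converging fit) maps to a distinct subclass of :class:`CamAngleError`
so callers — and the CLI — can separate expected failures from bugs.
"""


class CamAngleError(Exception):
    """Base class for all camangle errors."""


class ValidationError(CamAngleError):
    """A parameter object violates its invariants."""


class DimensionError(CamAngleError):
    """A grid or array has the wrong shape/dimensionality."""


class MaskFormatError(CamAngleError):
    """A mask file is unreadable as an axis-aligned 3D volume."""


class EmptyMaskError(CamAngleError):
    """The segmentation mask contains no foreground voxels."""


class DegenerateSurfaceError(CamAngleError):
    """The extracted surface is too small to be a femur."""


class LandmarkError(CamAngleError):
    """Initial head/neck landmark detection failed."""


class PartitionError(CamAngleError):
    """Head/neck surface partition produced an empty region."""


class SphereFitError(CamAngleError):
    """RANSAC sphere fitting failed or found too few inliers."""


class NeckAxisError(CamAngleError):
    """Minimal-circumference neck axis refinement failed."""


class SliceAnchorError(CamAngleError):
    """The azimuth reference direction is parallel to the neck axis."""


class RoundnessMapError(CamAngleError):
    """Too much of the roundness map is unsampled; geometry likely wrong."""


class TableFormatError(CamAngleError):
    """A measurement table violates the long-format schema."""


class SampleSizeError(CamAngleError):
    """Too few units for the requested statistic."""
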