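"""Frame preprocessing: orientation alignment, smoothing, segmentation, crop.

The processing chain for one frame is: align so the biceps side faces left,
moving-average smoothing, Otsu global thresholding to separate the warm arm
from the cool background, largest-connected-component selection with hole
filling, and a tight crop to the arm's bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigError, DegenerateHistogramError, SegmentationError
from .thermal_io import ThermalFrame


@dataclass(frozen=True)
class ArmMask:
    """Boolean foreground mask of the segmented arm."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask, dtype=bool)
        if arr.ndim != 2:
            raise SegmentationError(f"mask must be 2-D, got shape {arr.shape}")
        if not arr.any():
            raise SegmentationError("mask is empty")
        object.__setattr__(self, "mask", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1), half-open, of the tight bounding box."""
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1


def align_frame(frame: ThermalFrame, arm_side: str) -> ThermalFrame:
    """Orient the frame so the biceps side is on the left.

    Left-arm frames already satisfy the convention and pass through
    unchanged; right-arm frames are mirrored horizontally.  The mirror is an
    involution: applying it twice restores the original.
    """
    if arm_side not in ("left", "right"):
        raise ConfigError(f"arm_side must be 'left' or 'right', got {arm_side!r}")
    if arm_side == "left":
        return frame
    return ThermalFrame(np.ascontiguousarray(frame.temperatures[:, ::-1]), frame.timestamp_s)


def smooth(frame: ThermalFrame, kernel_rows: int = 3, kernel_cols: int = 3) -> ThermalFrame:
    """Moving-average filter with edge replication at the borders."""
    for k in (kernel_rows, kernel_cols):
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"kernel dimensions must be odd and positive, got {k}")
    out = ndimage.uniform_filter(frame.temperatures, size=(kernel_rows, kernel_cols), mode="nearest")
    return ThermalFrame(out, frame.timestamp_s)


def otsu_threshold(frame: ThermalFrame, nbins: int = 256) -> float:
    """Otsu's global threshold over a 256-bin histogram of the frame.

    Returns the temperature (°C) maximizing the between-class variance of
    the two classes it induces.  A constant frame has no meaningful
    histogram and raises :class:`DegenerateHistogramError`.
    """
    values = frame.temperatures
    if np.unique(values).size < 2:
        raise DegenerateHistogramError("frame is constant; no threshold exists")
    return float(threshold_otsu(values, nbins=nbins))


def segment_arm(frame: ThermalFrame, mask_override: np.ndarray | None = None) -> ArmMask:
    """Segment the arm: Otsu foreground, largest component, holes filled.

    Skin is warmer than the background, so the foreground is the set of
    pixels strictly above the Otsu threshold.  ``mask_override`` replaces the
    automatic result entirely (stand-in for the study's manual touch-up).
    """
    if mask_override is not None:
        return ArmMask(np.asarray(mask_override, dtype=bool))
    thr = otsu_threshold(frame)
    fg = frame.temperatures > thr
    if not fg.any():
        raise SegmentationError("no pixels above the Otsu threshold")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        fg = labels == keep
    fg = ndimage.binary_fill_holes(fg)
    return ArmMask(fg)


def crop_roi(frame: ThermalFrame, mask: ArmMask) -> tuple[ThermalFrame, ArmMask]:
    """Crop frame and mask to the mask's tight bounding box."""
    if frame.shape != mask.shape:
        raise SegmentationError(
            f"frame shape {frame.shape} does not match mask shape {mask.shape}"
        )
    r0, r1, c0, c1 = mask.bounding_box()
    return (
        ThermalFrame(frame.temperatures[r0:r1, c0:c1].copy(), frame.timestamp_s),
        ArmMask(mask.mask[r0:r1, c0:c1].copy()),
    )


def preprocess_frame(
    frame: ThermalFrame,
    arm_side: str = "left",
    kernel: tuple[int, int] = (3, 3),
    mask_override: np.ndarray | None = None,
) -> tuple[ThermalFrame, ArmMask]:
    """Full chain: align, smooth, segment, crop.  Returns (roi, roi_mask)."""
    aligned = align_frame(frame, arm_side)
    smoothed = smooth(aligned, *kernel)
    mask = segment_arm(smoothed, mask_override=mask_override)
    return crop_roi(smoothed, mask)
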