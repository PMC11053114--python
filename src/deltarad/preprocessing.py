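"""Fiducial-artifact masking and fixed-bin-number intensity discretization.

Image processing is deliberately minimal: no resampling, no range
re-segmentation, no filtering.  The ROI intensities are discretized with a
fixed bin number (default 256, i.e. 8 bit) over the per-image in-mask
min/max before any texture matrix is built.  Bright fiducial-marker
artifacts inside the prostate are excluded by thresholding plus an
isotropic millimetre dilation; the effective ROI for feature extraction is
the contour minus that exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ROIMask, VolumeImage, check_same_grid


class EmptyROIError(ValueError):
    """An operation that requires in-mask voxels received an empty mask."""


@dataclass(frozen=True)
class QuantizationConfig:
    """Fixed-bin-number grey-level discretization settings.

    ``n_bins``
        Number of grey levels (default 256).  The in-mask intensity range
        is split into ``n_bins`` equal-width bins; levels are 1-based.
    ``range_policy``
        Only ``"roi_min_max"`` is supported: the discretization range is
        the in-mask min/max of each image individually.
    """

    n_bins: int = 256
    range_policy: str = "roi_min_max"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.range_policy != "roi_min_max":
            raise ValueError(f"unknown range_policy {self.range_policy!r}")


@dataclass(frozen=True)
class QuantizedROI:
    """Discretized ROI: integer levels in 1..n_bins inside the effective mask.

    ``levels`` is 0 outside the mask.  ``flat`` flags the degenerate case of
    a constant in-mask intensity, where every level is set to 1.
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    spacing: tuple[float, float, float]
    flat: bool = False

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _dilation_structure(dilation_mm: float, spacing) -> np.ndarray | None:
    """Ellipsoidal structuring element with per-axis radius dilation_mm / spacing."""
    radii = [int(np.floor(dilation_mm / s + 1e-9)) for s in spacing]
    if all(r == 0 for r in radii):
        return None
    zz, yy, xx = np.ogrid[
        -radii[0] : radii[0] + 1, -radii[1] : radii[1] + 1, -radii[2] : radii[2] + 1
    ]
    # physical distance from the centre, in mm
    dist2 = (
        (zz * spacing[0]) ** 2 + (yy * spacing[1]) ** 2 + (xx * spacing[2]) ** 2
    )
    return dist2 <= dilation_mm**2 + 1e-9


def build_fiducial_mask(
    image: VolumeImage,
    roi: ROIMask,
    intensity_threshold: float,
    dilation_mm: float = 2.0,
) -> ROIMask:
    """Exclusion mask for bright fiducial artifacts inside the ROI.

    In-ROI voxels strictly above ``intensity_threshold`` are dilated by an
    ellipsoid of radius ``dilation_mm`` (converted per axis to voxels) and
    intersected with the ROI.  The effective mask for feature extraction is
    ``roi AND NOT exclusion``.

    Raises
    ------
    EmptyROIError
        If the ROI is empty, or the exclusion covers the whole ROI.
    """
    check_same_grid(image, roi)
    if roi.is_empty:
        raise EmptyROIError("ROI is empty")
    if dilation_mm < 0:
        raise ValueError("dilation_mm must be >= 0")
    bright = roi.data & (image.data > intensity_threshold)
    if bright.any():
        struct = _dilation_structure(dilation_mm, image.spacing)
        if struct is not None:
            bright = ndimage.binary_dilation(bright, structure=struct)
        bright &= roi.data
    excl = ROIMask(bright, roi.spacing)
    if (roi.data & ~excl.data).sum() == 0:
        raise EmptyROIError("fiducial exclusion covers the entire ROI")
    return excl


def effective_mask(roi: ROIMask, fiducial_excl: ROIMask | None) -> ROIMask:
    """ROI minus fiducial exclusion (identity when no exclusion is given)."""
    if fiducial_excl is None:
        return roi
    check_same_grid(roi, fiducial_excl)
    return ROIMask(roi.data & ~fiducial_excl.data, roi.spacing)


def quantize_fixed_bin_number(
    image: VolumeImage, mask: ROIMask, config: QuantizationConfig | None = None
) -> QuantizedROI:
    """Discretize in-mask intensities into ``n_bins`` equal-width levels.

    With g_min/g_max the in-mask extremes,
    ``level(v) = floor(n_bins * (g(v) - g_min) / (g_max - g_min)) + 1``,
    clamped so the maximum maps to ``n_bins``.  A flat ROI (g_max == g_min)
    maps every voxel to level 1 and sets the ``flat`` flag.
    """
    config = config or QuantizationConfig()
    check_same_grid(image, mask)
    if mask.is_empty:
        raise EmptyROIError("effective mask is empty")
    m = mask.data
    g = image.data[m]
    g_min, g_max = float(g.min()), float(g.max())
    levels = np.zeros(image.shape, dtype=np.int32)
    if g_max == g_min:
        levels[m] = 1
        return QuantizedROI(levels, m.copy(), config.n_bins, image.spacing, flat=True)
    lv = np.floor(config.n_bins * (image.data[m] - g_min) / (g_max - g_min)).astype(
        np.int32
    ) + 1
    np.clip(lv, 1, config.n_bins, out=lv)
    levels[m] = lv
    return QuantizedROI(levels, m.copy(), config.n_bins, image.spacing, flat=False)


def roi_volume(mask: ROIMask) -> tuple[float, int]:
    """(volume in mm^3, voxel count) of a non-empty mask."""
    if mask.is_empty:
        raise EmptyROIError("cannot compute volume of an empty mask")
    n = mask.n_voxels
    return n * mask.voxel_volume_mm3, n
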