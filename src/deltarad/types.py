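"""Core grid containers shared across the pipeline.

A per-fraction image is a 3D scalar grid with anisotropic voxel spacing in
millimetres; regions of interest (prostate contour, fiducial-artifact
exclusion) are binary masks on the same grid.  Axis order is (z, y, x) and
``spacing`` follows the same order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Spacing = tuple[float, float, float]


class GridMismatchError(ValueError):
    """Two grid objects do not share shape and voxel spacing."""


@dataclass(frozen=True)
class VolumeImage:
    """3D grayscale volume with voxel spacing in mm (z, y, x order)."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"image must be 3D, got ndim={arr.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIMask:
    """Binary mask on the same grid as its image."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={arr.ndim}")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "data", arr.astype(bool))
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


def check_same_grid(*objs: VolumeImage | ROIMask) -> None:
    """Raise :class:`GridMismatchError` unless all objects share shape and spacing."""
    ref = objs[0]
    for o in objs[1:]:
        if o.shape != ref.shape or not np.allclose(o.spacing, ref.spacing):
            raise GridMismatchError(
                f"grid mismatch: {o.shape}@{o.spacing} vs {ref.shape}@{ref.spacing}"
            )
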