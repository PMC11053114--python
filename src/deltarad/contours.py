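"""Contour agreement metrics (TG-132 style) between mask pairs.

Used as pipeline QA on automated vs manual prostate contours: Dice
similarity coefficient (DSC), mean distance-to-agreement (MDA, symmetrized
over both directed surface-distance means), centre-of-mass displacement,
and signed percent volume difference relative to the reference (manual)
mask.  Surfaces are voxel boundaries; distances are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocessing import EmptyROIError
from .types import ROIMask, check_same_grid


@dataclass(frozen=True)
class ContourAgreement:
    dsc: float
    mda_mm: float
    delta_com_mm: float
    delta_vol_pct: float


def dice(a: ROIMask, b: ROIMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    check_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyROIError("dice requires two non-empty masks")
    inter = int((a.data & b.data).sum())
    return 2.0 * inter / (a.n_voxels + b.n_voxels)


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3)), border_value=0)
    return mask & ~eroded


def _surface_points_mm(mask: ROIMask) -> np.ndarray:
    pts = np.argwhere(_boundary(mask.data)).astype(float)
    return pts * np.asarray(mask.spacing)


def mean_distance_to_agreement(a: ROIMask, b: ROIMask) -> float:
    """Symmetric MDA: average of the two directed mean surface distances (mm)."""
    check_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyROIError("MDA requires two non-empty masks")
    pa = _surface_points_mm(a)
    pb = _surface_points_mm(b)
    from scipy.spatial import cKDTree

    da = cKDTree(pb).query(pa)[0].mean()
    db = cKDTree(pa).query(pb)[0].mean()
    return float((da + db) / 2.0)


def com_difference(a: ROIMask, b: ROIMask) -> float:
    """Euclidean distance between unweighted voxel centroids, in mm."""
    check_same_grid(a, b)
    if a.is_empty or b.is_empty:
        raise EmptyROIError("centroid requires non-empty masks")
    sp = np.asarray(a.spacing)
    ca = np.argwhere(a.data).mean(axis=0) * sp
    cb = np.argwhere(b.data).mean(axis=0) * sp
    return float(np.linalg.norm(ca - cb))


def volume_difference_pct(a: ROIMask, b: ROIMask) -> float:
    """Signed percent volume difference 100*(|B|-|A|)/|A|, reference = a (manual)."""
    check_same_grid(a, b)
    if a.is_empty:
        raise EmptyROIError("reference mask is empty")
    va = a.n_voxels * a.voxel_volume_mm3
    vb = b.n_voxels * b.voxel_volume_mm3
    return float(100.0 * (vb - va) / va)


def agreement(manual: ROIMask, automated: ROIMask) -> ContourAgreement:
    """All four TG-132 metrics for one manual/automated pair."""
    return ContourAgreement(
        dsc=dice(manual, automated),
        mda_mm=mean_distance_to_agreement(manual, automated),
        delta_com_mm=com_difference(manual, automated),
        delta_vol_pct=volume_difference_pct(manual, automated),
    )
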