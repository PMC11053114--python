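"""3D texture matrices and the radiomic feature roster.

Five feature classes are computed on a discretized ROI: grey-level
co-occurrence (GLCM), grey-level run length (GLRLM), grey-level size zone
(GLSZM), neighbourhood grey-tone difference (NGTDM), and first-order
("Global") statistics on the raw intensities.  Matrices are accumulated
over the 13 unique 3D directions (or the 26-neighbourhood where the class
calls for it), counting only voxel pairs fully inside the effective mask,
then aggregated into a single matrix per class before features are taken.

Six features known to scale with ROI volume carry volume-normalized (VN)
companions: ``value * n_voxels ** k`` with k = -1 for the grey-level /
run-length non-uniformities (raw values grow linearly with voxel count)
and k = +1 for NGTDM Coarseness and Strength (raw values shrink as 1/N).

Degenerate textures (flat ROI, zero variance) yield explicit missing
values (NaN), never silent zeros, except where a finite convention is
standard (Coarseness capped, NGTDM Contrast 0 on a single grey level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import measure

from .preprocessing import (
    EmptyROIError,
    QuantizationConfig,
    QuantizedROI,
    effective_mask,
    quantize_fixed_bin_number,
    roi_volume,
)
from .types import ROIMask, VolumeImage, check_same_grid

# The 13 unique displacement directions of a 3D grid (positive half of the
# 26-neighbourhood), in (z, y, x) voxel offsets.
DIRECTIONS_3D_13: tuple[tuple[int, int, int], ...] = (
    (0, 0, 1),
    (0, 1, 0),
    (1, 0, 0),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

COARSENESS_CAP = 1e6

# value * n_voxels**k leaves the feature approximately volume-invariant
VOLUME_NORMALIZATION_EXPONENTS: dict[str, int] = {
    "GLRLM_GLN": -1,
    "GLRLM_RLN": -1,
    "GLSZM_GLN": -1,
    "NGTDM_Coarseness": +1,
    "NGTDM_Busyness": -1,
    "NGTDM_Strength": +1,
}

GLOBAL_FEATURES = ("Global_Mean", "Global_Variance", "Global_Skewness", "Global_Kurtosis")
GLCM_FEATURES = (
    "GLCM_Correlation",
    "GLCM_Contrast",
    "GLCM_Energy",
    "GLCM_Homogeneity",
    "GLCM_Entropy",
    "GLCM_Dissimilarity",
    "GLCM_SumAverage",
    "GLCM_ClusterShade",
)
GLRLM_FEATURES = (
    "GLRLM_SRE",
    "GLRLM_LRE",
    "GLRLM_GLN",
    "GLRLM_RLN",
    "GLRLM_RP",
    "GLRLM_LGRE",
    "GLRLM_HGRE",
    "GLRLM_SRHGE",
)
GLSZM_FEATURES = (
    "GLSZM_SZE",
    "GLSZM_LZE",
    "GLSZM_GLN",
    "GLSZM_ZSN",
    "GLSZM_ZP",
    "GLSZM_ZSV",
    "GLSZM_LGZE",
    "GLSZM_HGZE",
    "GLSZM_SZLGE",
    "GLSZM_LZLGE",
    "GLSZM_LZHGE",
)
NGTDM_FEATURES = (
    "NGTDM_Coarseness",
    "NGTDM_Contrast",
    "NGTDM_Busyness",
    "NGTDM_Complexity",
    "NGTDM_Strength",
)
VN_FEATURES = tuple(f"{name}_VN" for name in VOLUME_NORMALIZATION_EXPONENTS)

#: The default roster: 36 base features over five classes plus the six
#: volume-normalized companions = 42 radiomic features.
DEFAULT_ROSTER: tuple[str, ...] = (
    GLOBAL_FEATURES + GLCM_FEATURES + GLRLM_FEATURES + GLSZM_FEATURES + NGTDM_FEATURES + VN_FEATURES
)

COVARIATES = ("ProstateVolume",)


@dataclass(frozen=True)
class TextureMatrix:
    """Aggregated texture matrix of one class.

    For GLCM the matrix is symmetrized counts normalized to probabilities;
    for GLRLM/GLSZM raw counts with row = grey level (1-based) and column =
    run length / zone size (1-based).  For NGTDM the per-level vectors
    ``n_i``, ``p_i``, ``s_i`` are stored instead of a 2D matrix.
    """

    kind: str
    matrix: np.ndarray | None = None
    n_i: np.ndarray | None = None
    p_i: np.ndarray | None = None
    s_i: np.ndarray | None = None
    aggregation: str = "sum over 13 unique 3D directions"


@dataclass
class FeatureVector:
    """Named radiomic feature values for one fraction/contour.

    Missing (degenerate) features are NaN.  ``meta`` records provenance
    (patient, fraction index, contour type).
    """

    values: dict[str, float]
    n_voxels: int
    meta: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# matrix builders
# ---------------------------------------------------------------------------


def _pair_slices(shape, d):
    """Slices (source, shifted) selecting all voxel pairs (v, v + d) in bounds."""
    src, dst = [], []
    for n, step in zip(shape, d):
        if step == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif step > 0:
            src.append(slice(0, n - step))
            dst.append(slice(step, n))
        else:
            src.append(slice(-step, n))
            dst.append(slice(0, n + step))
    return tuple(src), tuple(dst)


def glcm(q: QuantizedROI, distance_voxels: int = 1) -> TextureMatrix:
    """Grey-level co-occurrence matrix at a fixed voxel distance.

    Pairs are counted along the 13 unique directions scaled by
    ``distance_voxels`` (offsets in voxel units; anisotropic spacing is
    ignored for neighbour definitions), summed, symmetrized, and normalized
    to probabilities.
    """
    if distance_voxels < 1:
        raise ValueError("distance_voxels must be >= 1")
    L, m = q.levels, q.mask
    n = int(L.max())
    counts = np.zeros((n, n), dtype=np.int64)
    for d in DIRECTIONS_3D_13:
        dd = tuple(distance_voxels * c for c in d)
        src, dst = _pair_slices(L.shape, dd)
        both = m[src] & m[dst]
        a = L[src][both] - 1
        b = L[dst][both] - 1
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise EmptyROIError("no in-mask voxel pairs (single-voxel or empty ROI)")
    return TextureMatrix(kind="GLCM", matrix=counts / total)


def glrlm(q: QuantizedROI) -> TextureMatrix:
    """Grey-level run length matrix over the 13 unique 3D directions.

    A run is a maximal sequence of equal-level in-mask voxels along a
    direction; runs truncate at the mask boundary.  Each run is counted
    once per direction.
    """
    L, m = q.levels, q.mask
    if not m.any():
        raise EmptyROIError("empty ROI")
    n_levels = int(L.max())
    max_run = max(L.shape)
    # generous run-length bound along diagonals is still max(shape)
    counts = np.zeros((n_levels, max_run), dtype=np.int64)
    for d in DIRECTIONS_3D_13:
        same = np.zeros(L.shape, dtype=bool)  # same[v]: v+d in mask with equal level
        src, dst = _pair_slices(L.shape, d)
        same[src] = m[src] & m[dst] & (L[src] == L[dst])
        prev_same = np.zeros(L.shape, dtype=bool)  # v-d in mask with equal level
        nd = tuple(-c for c in d)
        src_b, dst_b = _pair_slices(L.shape, nd)
        prev_same[src_b] = m[src_b] & m[dst_b] & (L[src_b] == L[dst_b])
        starts = np.argwhere(m & ~prev_same)
        if starts.size == 0:
            continue
        lengths = np.ones(len(starts), dtype=np.int64)
        pos = starts.copy()
        active = same[tuple(pos.T)]
        dvec = np.asarray(d)
        while active.any():
            pos[active] += dvec
            lengths[active] += 1
            nxt = same[tuple(pos[active].T)]
            active[active] = nxt
        lev = L[tuple(starts.T)]
        np.add.at(counts, (lev - 1, lengths - 1), 1)
    # trim trailing all-zero run-length columns
    nz = np.nonzero(counts.any(axis=0))[0]
    counts = counts[:, : nz[-1] + 1] if nz.size else counts[:, :1]
    return TextureMatrix(kind="GLRLM", matrix=counts)


def glszm(q: QuantizedROI) -> TextureMatrix:
    """Grey-level size zone matrix (zones = 26-connected equal-level components)."""
    L, m = q.levels, q.mask
    if not m.any():
        raise EmptyROIError("empty ROI")
    lab = measure.label(L, background=0, connectivity=3)
    n_zones = lab.max()
    sizes = np.bincount(lab.ravel())[1:]
    # grey level of each zone: level at the first voxel of the zone
    flat_lab = lab.ravel()
    order = np.argsort(flat_lab, kind="stable")
    first_idx = order[np.searchsorted(flat_lab[order], np.arange(1, n_zones + 1))]
    zone_levels = L.ravel()[first_idx]
    n_levels = int(L.max())
    counts = np.zeros((n_levels, int(sizes.max())), dtype=np.int64)
    np.add.at(counts, (zone_levels - 1, sizes - 1), 1)
    return TextureMatrix(kind="GLSZM", matrix=counts, aggregation="26-connected zones")


def ngtdm(q: QuantizedROI) -> TextureMatrix:
    """Neighbourhood grey-tone difference vectors.

    For each level i present: ``n_i`` counts in-mask voxels of level i with
    at least one in-mask 26-neighbour, ``s_i`` sums ``|i - mean neighbour
    level|`` over those voxels, and ``p_i = n_i / sum(n)``.
    """
    L, m = q.levels, q.mask
    if not m.any():
        raise EmptyROIError("empty ROI")
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    mf = m.astype(float)
    nb_cnt = ndimage.convolve(mf, kernel, mode="constant", cval=0.0)
    nb_sum = ndimage.convolve(L.astype(float) * mf, kernel, mode="constant", cval=0.0)
    valid = m & (nb_cnt > 0)
    n_levels = int(L.max())
    n_i = np.zeros(n_levels, dtype=np.int64)
    s_i = np.zeros(n_levels, dtype=float)
    lev = L[valid] - 1
    diff = np.abs(L[valid] - nb_sum[valid] / nb_cnt[valid])
    np.add.at(n_i, lev, 1)
    np.add.at(s_i, lev, diff)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i.astype(float)
    return TextureMatrix(
        kind="NGTDM", n_i=n_i, p_i=p_i, s_i=s_i, aggregation="26-neighbourhood"
    )


# ---------------------------------------------------------------------------
# feature formulas
# ---------------------------------------------------------------------------


def glcm_features(m: TextureMatrix) -> dict[str, float]:
    if m.kind != "GLCM":
        raise ValueError("expected a GLCM matrix")
    p = m.matrix
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())  # symmetric matrix: mu_x == mu_y
    var = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(var)
    out: dict[str, float] = {}
    if sigma > 0:
        out["GLCM_Correlation"] = float(((ii * jj * p).sum() - mu * mu) / var)
    else:
        out["GLCM_Correlation"] = np.nan
    out["GLCM_Contrast"] = float(((ii - jj) ** 2 * p).sum())
    out["GLCM_Energy"] = float((p**2).sum())
    out["GLCM_Homogeneity"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    pz = p[p > 0]
    out["GLCM_Entropy"] = float(-(pz * np.log2(pz)).sum())
    out["GLCM_Dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["GLCM_SumAverage"] = float(((ii + jj) * p).sum())
    out["GLCM_ClusterShade"] = float((((ii + jj) - 2 * mu) ** 3 * p).sum())
    return out


def glrlm_features(m: TextureMatrix, n_voxels: int) -> dict[str, float]:
    if m.kind != "GLRLM":
        raise ValueError("expected a GLRLM matrix")
    r = m.matrix.astype(float)
    if r.sum() == 0:
        raise EmptyROIError("empty run-length matrix")
    nr = r.sum()
    i = np.arange(1, r.shape[0] + 1)[:, None]
    j = np.arange(1, r.shape[1] + 1)[None, :]
    out = {
        "GLRLM_SRE": float((r / j**2).sum() / nr),
        "GLRLM_LRE": float((r * j**2).sum() / nr),
        "GLRLM_GLN": float((r.sum(axis=1) ** 2).sum() / nr),
        "GLRLM_RLN": float((r.sum(axis=0) ** 2).sum() / nr),
        "GLRLM_RP": float(nr / (len(DIRECTIONS_3D_13) * n_voxels)),
        "GLRLM_LGRE": float((r / i**2).sum() / nr),
        "GLRLM_HGRE": float((r * i**2).sum() / nr),
        "GLRLM_SRHGE": float((r * i**2 / j**2).sum() / nr),
    }
    for name in ("GLRLM_GLN", "GLRLM_RLN"):
        out[f"{name}_VN"] = volume_normalize(name, out[name], n_voxels)
    return out


def glszm_features(m: TextureMatrix, n_voxels: int) -> dict[str, float]:
    if m.kind != "GLSZM":
        raise ValueError("expected a GLSZM matrix")
    z = m.matrix.astype(float)
    nz = z.sum()
    if nz == 0:
        raise EmptyROIError("empty size-zone matrix")
    i = np.arange(1, z.shape[0] + 1)[:, None]
    j = np.arange(1, z.shape[1] + 1)[None, :]
    pj = z / nz
    mu_size = float((pj * j).sum())
    out = {
        "GLSZM_SZE": float((z / j**2).sum() / nz),
        "GLSZM_LZE": float((z * j**2).sum() / nz),
        "GLSZM_GLN": float((z.sum(axis=1) ** 2).sum() / nz),
        "GLSZM_ZSN": float((z.sum(axis=0) ** 2).sum() / nz),
        "GLSZM_ZP": float(nz / n_voxels),
        "GLSZM_ZSV": float((pj * (j - mu_size) ** 2).sum()),
        "GLSZM_LGZE": float((z / i**2).sum() / nz),
        "GLSZM_HGZE": float((z * i**2).sum() / nz),
        "GLSZM_SZLGE": float((z / (i**2 * j**2)).sum() / nz),
        "GLSZM_LZLGE": float((z * j**2 / i**2).sum() / nz),
        "GLSZM_LZHGE": float((z * i**2 * j**2).sum() / nz),
    }
    out["GLSZM_GLN_VN"] = volume_normalize("GLSZM_GLN", out["GLSZM_GLN"], n_voxels)
    return out


def ngtdm_features(m: TextureMatrix, n_voxels: int) -> dict[str, float]:
    if m.kind != "NGTDM":
        raise ValueError("expected an NGTDM matrix")
    n_i, p_i, s_i = m.n_i, m.p_i, m.s_i
    present = p_i > 0
    levels = np.arange(1, len(p_i) + 1, dtype=float)
    n_total = n_i.sum()
    if n_total == 0:
        raise EmptyROIError("no valid NGTDM voxels")
    ng = int(present.sum())
    ps = float((p_i * s_i).sum())
    out: dict[str, float] = {}
    out["NGTDM_Coarseness"] = COARSENESS_CAP if ps <= 0 else min(1.0 / ps, COARSENESS_CAP)
    if ng > 1:
        ip = levels[present]
        pp = p_i[present]
        di = ip[:, None] - ip[None, :]
        out["NGTDM_Contrast"] = float(
            (pp[:, None] * pp[None, :] * di**2).sum()
            / (ng * (ng - 1))
            * (s_i.sum() / n_total)
        )
        denom_busy = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        out["NGTDM_Busyness"] = ps / denom_busy if denom_busy > 0 else 0.0
        si_p = s_i[present]
        out["NGTDM_Complexity"] = float(
            (
                np.abs(di)
                * (pp[:, None] * si_p[:, None] + pp[None, :] * si_p[None, :])
                / (pp[:, None] + pp[None, :])
            ).sum()
            / n_total
        )
        s_sum = float(s_i.sum())
        out["NGTDM_Strength"] = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum() / s_sum) if s_sum > 0 else 0.0
        )
    else:
        out["NGTDM_Contrast"] = 0.0
        out["NGTDM_Busyness"] = 0.0
        out["NGTDM_Complexity"] = 0.0
        out["NGTDM_Strength"] = 0.0
    for name in ("NGTDM_Coarseness", "NGTDM_Busyness", "NGTDM_Strength"):
        out[f"{name}_VN"] = volume_normalize(name, out[name], n_voxels)
    return out


def global_features(image: VolumeImage, mask: ROIMask) -> dict[str, float]:
    """First-order statistics on the raw (undiscretized) in-mask intensities.

    Skewness and kurtosis use central moments, ``m3 / m2**1.5`` and the
    non-excess ``m4 / m2**2``; both are NaN for a zero-variance ROI.
    """
    check_same_grid(image, mask)
    if mask.is_empty:
        raise EmptyROIError("empty mask")
    g = image.data[mask.data].astype(float)
    mu = float(g.mean())
    d = g - mu
    m2 = float((d**2).mean())
    out = {"Global_Mean": mu, "Global_Variance": m2}
    if m2 > 0 and len(g) >= 2:
        out["Global_Skewness"] = float((d**3).mean() / m2**1.5)
        out["Global_Kurtosis"] = float((d**4).mean() / m2**2)
    else:
        out["Global_Skewness"] = np.nan
        out["Global_Kurtosis"] = np.nan
    return out


def volume_normalize(name: str, value: float, n_voxels: int) -> float:
    """Apply the per-feature volume-power correction ``value * n_voxels**k``."""
    if name not in VOLUME_NORMALIZATION_EXPONENTS:
        raise KeyError(f"{name} has no volume-normalization exponent")
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    return float(value) * float(n_voxels) ** VOLUME_NORMALIZATION_EXPONENTS[name]


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------


def extract_all(
    image: VolumeImage,
    roi: ROIMask,
    fiducial_excl: ROIMask | None = None,
    qc: QuantizationConfig | None = None,
    glcm_distance: int = 1,
    roster: tuple[str, ...] = DEFAULT_ROSTER,
    meta: Mapping | None = None,
) -> FeatureVector:
    """Run preprocessing and all five feature classes on one fraction.

    A degenerate sub-computation marks only its own features missing; the
    rest of the vector survives.  ``ProstateVolume`` (mm^3 of the full
    contour, before fiducial exclusion) is attached as a covariate.
    """
    qc = qc or QuantizationConfig()
    eff = effective_mask(roi, fiducial_excl)
    if eff.is_empty:
        raise EmptyROIError("effective mask is empty after fiducial exclusion")
    q = quantize_fixed_bin_number(image, eff, qc)
    values: dict[str, float] = {}
    class_runs = (
        (lambda: glcm_features(glcm(q, glcm_distance)), GLCM_FEATURES),
        (lambda: glrlm_features(glrlm(q), q.n_voxels), GLRLM_FEATURES + ("GLRLM_GLN_VN", "GLRLM_RLN_VN")),
        (lambda: glszm_features(glszm(q), q.n_voxels), GLSZM_FEATURES + ("GLSZM_GLN_VN",)),
        (lambda: ngtdm_features(ngtdm(q), q.n_voxels), NGTDM_FEATURES + ("NGTDM_Coarseness_VN", "NGTDM_Busyness_VN", "NGTDM_Strength_VN")),
        (lambda: global_features(image, eff), GLOBAL_FEATURES),
    )
    for run, names in class_runs:
        try:
            values.update(run())
        except EmptyROIError:
            values.update({n: np.nan for n in names})
    vol, _ = roi_volume(roi)
    values["ProstateVolume"] = vol
    ordered = {name: values.get(name, np.nan) for name in roster}
    ordered["ProstateVolume"] = values["ProstateVolume"]
    return FeatureVector(values=ordered, n_voxels=q.n_voxels, meta=dict(meta or {}))
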