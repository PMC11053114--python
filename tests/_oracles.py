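"""Independent brute-force oracles used only by the test suite.

Every function here is a deliberately naive re-derivation (exhaustive
enumeration, explicit loops) of a quantity the package computes by a
faster route; the two must agree on small inputs.
"""

from __future__ import annotations

import itertools

import numpy as np

DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def _in_bounds(c, shape):
    return all(0 <= x < n for x, n in zip(c, shape))


def glcm_counts(levels: np.ndarray, mask: np.ndarray, distance: int = 1) -> np.ndarray:
    """Symmetric unnormalized co-occurrence counts by explicit pair enumeration."""
    n = int(levels.max())
    counts = np.zeros((n, n), dtype=np.int64)
    shape = levels.shape
    for c in itertools.product(*(range(s) for s in shape)):
        if not mask[c]:
            continue
        for d in DIRECTIONS:
            for sign in (1, -1):
                nb = tuple(x + sign * distance * dd for x, dd in zip(c, d))
                if _in_bounds(nb, shape) and mask[nb]:
                    counts[levels[c] - 1, levels[nb] - 1] += 1
    return counts


def glrlm_counts(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Run-length counts by walking every line in every direction."""
    shape = levels.shape
    n = int(levels.max())
    runs: list[tuple[int, int]] = []
    for d in DIRECTIONS:
        for c in itertools.product(*(range(s) for s in shape)):
            if not mask[c]:
                continue
            prev = tuple(x - dd for x, dd in zip(c, d))
            if (
                _in_bounds(prev, shape)
                and mask[prev]
                and levels[prev] == levels[c]
            ):
                continue  # not a run start
            length = 1
            cur = c
            while True:
                nxt = tuple(x + dd for x, dd in zip(cur, d))
                if _in_bounds(nxt, shape) and mask[nxt] and levels[nxt] == levels[cur]:
                    cur = nxt
                    length += 1
                else:
                    break
            runs.append((levels[c], length))
    max_len = max(l for _, l in runs)
    counts = np.zeros((n, max_len), dtype=np.int64)
    for lev, length in runs:
        counts[lev - 1, length - 1] += 1
    return counts


def glszm_counts(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size-zone counts by flood fill over 26-connected equal-level components."""
    shape = levels.shape
    n = int(levels.max())
    seen = np.zeros(shape, dtype=bool)
    zones: list[tuple[int, int]] = []
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for c in itertools.product(*(range(s) for s in shape)):
        if not mask[c] or seen[c]:
            continue
        lev = levels[c]
        stack, size = [c], 0
        seen[c] = True
        while stack:
            cur = stack.pop()
            size += 1
            for d in neighbors:
                nb = tuple(x + dd for x, dd in zip(cur, d))
                if (
                    _in_bounds(nb, shape)
                    and mask[nb]
                    and not seen[nb]
                    and levels[nb] == lev
                ):
                    seen[nb] = True
                    stack.append(nb)
        zones.append((lev, size))
    max_size = max(s for _, s in zones)
    counts = np.zeros((n, max_size), dtype=np.int64)
    for lev, size in zones:
        counts[lev - 1, size - 1] += 1
    return counts


def ngtdm_vectors(levels: np.ndarray, mask: np.ndarray):
    """(n_i, s_i, p_i) by explicit 26-neighbourhood loops."""
    shape = levels.shape
    n = int(levels.max())
    n_i = np.zeros(n, dtype=np.int64)
    s_i = np.zeros(n, dtype=float)
    neighbors = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for c in itertools.product(*(range(s) for s in shape)):
        if not mask[c]:
            continue
        vals = [
            levels[tuple(x + dd for x, dd in zip(c, d))]
            for d in neighbors
            if _in_bounds(tuple(x + dd for x, dd in zip(c, d)), shape)
            and mask[tuple(x + dd for x, dd in zip(c, d))]
        ]
        if not vals:
            continue
        i = levels[c]
        n_i[i - 1] += 1
        s_i[i - 1] += abs(i - float(np.mean(vals)))
    total = n_i.sum()
    p_i = n_i / total if total else n_i.astype(float)
    return n_i, s_i, p_i


def pair_count_auc(scores, labels) -> float:
    """AUC by exhaustive positive/negative pair counting with half-ties."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values by direct rule evaluation."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return adj


def mda_bruteforce(mask_a: np.ndarray, mask_b: np.ndarray, spacing) -> float:
    """Symmetric mean surface distance via all-pairs distances over boundary voxels."""

    def boundary(mask):
        pts = []
        shape = mask.shape
        for c in itertools.product(*(range(s) for s in shape)):
            if not mask[c]:
                continue
            on_edge = False
            for d in itertools.product((-1, 0, 1), repeat=3):
                if d == (0, 0, 0):
                    continue
                nb = tuple(x + dd for x, dd in zip(c, d))
                if not _in_bounds(nb, shape) or not mask[nb]:
                    on_edge = True
                    break
            if on_edge:
                pts.append(c)
        return np.asarray(pts, float) * np.asarray(spacing)

    pa, pb = boundary(mask_a), boundary(mask_b)
    d_ab = np.mean([np.min(np.linalg.norm(pb - p, axis=1)) for p in pa])
    d_ba = np.mean([np.min(np.linalg.norm(pa - p, axis=1)) for p in pb])
    return float((d_ab + d_ba) / 2.0)


def random_quantized_roi(rng: np.random.Generator, max_shape=(6, 6, 3), max_levels=8):
    """Random small levels/mask pair with a guaranteed non-trivial ROI."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    n_levels = int(rng.integers(2, max_levels + 1))
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.8
    if mask.sum() < 2:
        flat = rng.choice(np.prod(shape), size=2, replace=False)
        mask.ravel()[flat] = True
    levels[~mask] = 0
    return levels, mask
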