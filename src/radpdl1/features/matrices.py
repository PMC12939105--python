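"""Construction of the five texture matrices from a discretized ROI.

All neighbourhood definitions are 3D: co-occurrence and run-length use the
13 unique distance-1 directions (half of the 26-neighbourhood; the other
half is covered by symmetry), size zones and dependence use the full
26-connected neighbourhood.

Matrices are kept in sparse triplet form (cell coordinates + counts):
filtered images can span thousands of gray levels at a fixed bin width, so
dense level-by-level arrays would be quadratically wasteful while the
number of occupied cells stays bounded by the voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

#: the 13 unique direction offsets at infinity-norm distance 1
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

#: all 26 neighbour offsets
OFFSETS_26: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SparseGLCM:
    """Normalized symmetric co-occurrence matrix as occupied cells.

    ``i``/``j`` are 0-based level indices, ``p`` the cell probabilities
    (summing to 1); ``ng`` the total number of levels.
    """

    i: np.ndarray
    j: np.ndarray
    p: np.ndarray
    ng: int

    def dense(self) -> np.ndarray:
        out = np.zeros((self.ng, self.ng))
        out[self.i, self.j] = self.p
        return out


@dataclass
class SparseCounts:
    """Generic (level, size) count matrix in triplet form.

    Used for run-length (size = run length), size-zone (size = zone
    voxels) and dependence (size = dependence) matrices.  ``level`` is
    0-based; ``size`` carries the actual 1-based size values.
    """

    level: np.ndarray
    size: np.ndarray
    count: np.ndarray
    ng: int
    n_voxels: int

    @property
    def total(self) -> float:
        return float(self.count.sum())


def _shifted_view(a: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """Array whose value at v is a[v + d]; out-of-grid positions -> fill."""
    out = np.full_like(a, fill)
    src, dst = [], []
    for ax, step in enumerate(d):
        n = a.shape[ax]
        if step >= 0:
            src.append(slice(step, n))
            dst.append(slice(0, n - step))
        else:
            src.append(slice(0, n + step))
            dst.append(slice(-step, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def glcm_per_direction(droi) -> list[SparseGLCM]:
    """Symmetric, normalised GLCM for each of the 13 directions.

    Directions with no valid voxel pair inside the mask are skipped.
    """
    ng = droi.n_levels
    lv, mask = droi.levels, droi.mask
    out = []
    for d in DIRECTIONS_13:
        nb_lv = _shifted_view(lv, d, 0)
        nb_ok = _shifted_view(mask, d, False)
        pair = mask & nb_ok
        if not pair.any():
            continue
        a = (lv[pair] - 1).astype(np.int64)
        b = (nb_lv[pair] - 1).astype(np.int64)
        # symmetrize by adding the reversed pairs
        codes = np.concatenate([a * ng + b, b * ng + a])
        uniq, counts = np.unique(codes, return_counts=True)
        p = counts.astype(np.float64) / counts.sum()
        out.append(SparseGLCM(uniq // ng, uniq % ng, p, ng))
    return out


def _triplets(levels0: np.ndarray, sizes1: np.ndarray, ng: int,
              n_voxels: int) -> SparseCounts:
    base = int(sizes1.max()) + 1
    codes = levels0.astype(np.int64) * base + sizes1
    uniq, counts = np.unique(codes, return_counts=True)
    return SparseCounts(uniq // base, uniq % base,
                        counts.astype(np.float64), ng, n_voxels)


def glrlm_per_direction(droi) -> list[SparseCounts]:
    """Run-length counts (level, run length) for each of 13 directions."""
    ng = droi.n_levels
    lv, mask = droi.levels, droi.mask
    max_len = max(lv.shape)
    n_vox = int(mask.sum())
    out = []
    for d in DIRECTIONS_13:
        nb_lv = _shifted_view(lv, d, 0)
        nb_ok = _shifted_view(mask, d, False)
        same = mask & nb_ok & (lv == nb_lv)  # run continues at v+d
        # dynamic programming: runlen[v] = 1 + runlen[v+d] while same
        runlen = np.ones(lv.shape, dtype=np.int64)
        for _ in range(max_len):
            ext = np.where(same, _shifted_view(runlen, d, 0) + 1, 1)
            if np.array_equal(ext, runlen):
                break
            runlen = ext
        # a run starts at v when v-d does not continue into v
        prev_same = _shifted_view(same, tuple(-s for s in d), False)
        start = mask & ~prev_same
        out.append(_triplets(lv[start] - 1, runlen[start], ng, n_vox))
    return out


def glszm(droi) -> SparseCounts:
    """Size-zone counts (level, zone size); zones are 26-connected."""
    ng = droi.n_levels
    n_vox = int(droi.mask.sum())
    levels0, sizes = [], []
    occupied = np.unique(droi.levels[droi.mask])
    for level in occupied:
        comp, n_comp = ndimage.label(droi.levels == level,
                                     structure=_STRUCT_26)
        if n_comp == 0:
            continue
        zone_sizes = np.bincount(comp.ravel())[1:]
        levels0.append(np.full(zone_sizes.size, level - 1, dtype=np.int64))
        sizes.append(zone_sizes.astype(np.int64))
    return _triplets(np.concatenate(levels0), np.concatenate(sizes),
                     ng, n_vox)


def gldm(droi, alpha: int = 0) -> SparseCounts:
    """Dependence counts (level, dependence).

    The dependence of a voxel is 1 + the number of its in-mask
    26-neighbours whose level differs by at most ``alpha`` (the centre
    voxel always counts, so dependence >= 1).
    """
    lv, mask = droi.levels, droi.mask
    dep = np.zeros(lv.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb_lv = _shifted_view(lv, d, 0)
        nb_ok = _shifted_view(mask, d, False)
        dep += (nb_ok & (np.abs(nb_lv - lv) <= alpha)).astype(np.int64)
    return _triplets(lv[mask] - 1, dep[mask] + 1, droi.n_levels,
                     int(mask.sum()))


def ngtdm(droi) -> tuple[np.ndarray, np.ndarray, int]:
    """Neighbourhood gray-tone difference vectors.

    Returns ``(n_i, s_i, n_valid)`` indexed by level-1, where ``n_i`` counts
    masked voxels of level i having at least one in-mask neighbour, ``s_i``
    sums |i - mean neighbour level| over those voxels, and ``n_valid`` is
    their total.
    """
    lv, mask = droi.levels, droi.mask
    ng = droi.n_levels
    nb_sum = np.zeros(lv.shape, dtype=np.float64)
    nb_cnt = np.zeros(lv.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb_lv = _shifted_view(lv, d, 0)
        nb_ok = _shifted_view(mask, d, False)
        nb_sum += np.where(nb_ok, nb_lv, 0)
        nb_cnt += nb_ok.astype(np.int64)
    valid = mask & (nb_cnt > 0)
    avg = nb_sum[valid] / nb_cnt[valid]
    diff = np.abs(lv[valid] - avg)
    lev0 = lv[valid] - 1
    n_i = np.bincount(lev0, minlength=ng).astype(np.float64)
    s_i = np.bincount(lev0, weights=diff, minlength=ng)
    return n_i, s_i, int(valid.sum())
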