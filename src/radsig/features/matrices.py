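"""Construction of the five gray-level texture matrices.

All constructions operate on an integer gray-level volume (0 outside the
ROI, levels 1..Ng inside) and are fully vectorized:

* GLCM — symmetric co-occurrence counts for each of the 13 unique 3D
  direction pairs at a configurable voxel distance;
* GLRLM — run-length counts per direction, encoded by sorting the ROI
  voxels along each direction's lines and run-length-encoding the result;
* GLSZM — zone-size counts over 26-connected components of equal level;
* GLDM — dependence counts: for each voxel, the number of its 26
  neighbours (inside the ROI) whose level differs by at most ``alpha``;
* NGTDM — per-level (count, probability, absolute difference from the
  neighbourhood mean) triples.

Row/column conventions: gray levels index rows (level i at row i-1); run
length l / zone size z sit at column l-1 / z-1; GLDM columns are the raw
neighbour counts 0..26.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "glcm_matrices",
    "glrlm_matrices",
    "glszm_matrix",
    "gldm_matrix",
    "ngtdm_table",
]

# 13 unique 3D directions: all 26 neighbour offsets modulo sign, keeping the
# representative whose first nonzero component is positive.
DIRECTIONS_13 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

_ALL_26 = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
)


def _offset_slices(offset, shape):
    """Slices (src, dst) so that arr[dst] is arr[src] shifted by ``offset``."""
    src, dst = [], []
    for o, n in zip(offset, shape):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def glcm_matrices(gray: np.ndarray, ng: int, distance: int = 1) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction."""
    mats = []
    for d in DIRECTIONS_13:
        off = tuple(distance * c for c in d)
        src, dst = _offset_slices(off, gray.shape)
        a, b = gray[src], gray[dst]
        valid = (a > 0) & (b > 0)
        idx = (a[valid] - 1) * ng + (b[valid] - 1)
        counts = np.bincount(idx, minlength=ng * ng).reshape(ng, ng)
        mats.append(counts + counts.T)
    return mats


def glrlm_matrices(gray: np.ndarray, ng: int) -> list[np.ndarray]:
    """Run-length count matrices P(level, run length), one per direction."""
    coords = np.argwhere(gray > 0)
    levels = gray[gray > 0]
    n_roi = len(coords)
    mats = []
    if n_roi == 0:
        raise ValueError("empty ROI")
    i, j, k = coords.T
    big = max(gray.shape) + 2
    for d in DIRECTIONS_13:
        # position of each voxel along its line; the first nonzero component
        # of d is +1, so t strictly increases along the run direction
        axis = 0 if d[0] else (1 if d[1] else 2)
        t = coords[:, axis]
        line = (
            ((i - t * d[0]) + big) * (3 * big) ** 2
            + ((j - t * d[1]) + big) * (3 * big)
            + ((k - t * d[2]) + big)
        )
        order = np.lexsort((t, line))
        lv, tv, gv = line[order], t[order], levels[order]
        # a run breaks where the line changes, positions skip, or level changes
        brk = np.ones(n_roi, dtype=bool)
        brk[1:] = (lv[1:] != lv[:-1]) | (tv[1:] != tv[:-1] + 1) | (gv[1:] != gv[:-1])
        starts = np.flatnonzero(brk)
        lengths = np.diff(np.append(starts, n_roi))
        run_levels = gv[starts]
        nr = int(lengths.max())
        idx = (run_levels - 1) * nr + (lengths - 1)
        mats.append(np.bincount(idx, minlength=ng * nr).reshape(ng, nr))
    return mats


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(gray: np.ndarray, ng: int) -> np.ndarray:
    """Zone-size count matrix P(level, zone size) over 26-connected zones."""
    rows = []
    max_size = 1
    for level in range(1, ng + 1):
        lab, nlab = ndimage.label(gray == level, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:] if nlab else np.array([], dtype=int)
        rows.append(sizes)
        if sizes.size:
            max_size = max(max_size, int(sizes.max()))
    P = np.zeros((ng, max_size), dtype=np.int64)
    for r, sizes in enumerate(rows):
        if sizes.size:
            P[r] = np.bincount(sizes - 1, minlength=max_size)[:max_size]
    return P


def gldm_matrix(gray: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P(level, d), d = dependent 26-neighbours (0..26)."""
    mask = gray > 0
    dep = np.zeros(gray.shape, dtype=np.int64)
    for off in _ALL_26:
        src, dst = _offset_slices(off, gray.shape)
        ok = mask[src] & mask[dst] & (np.abs(gray[src] - gray[dst]) <= alpha)
        dep[src] += ok
    levels = gray[mask]
    deps = dep[mask]
    idx = (levels - 1) * 27 + deps
    return np.bincount(idx, minlength=ng * 27).reshape(ng, 27)


def ngtdm_table(gray: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (n_i, p_i, s_i): counts, probabilities, and the summed
    absolute difference between the level and the mean of its in-ROI
    26-neighbourhood.  Voxels with no in-ROI neighbour are excluded."""
    mask = gray > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0.0
    nb_cnt = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant")
    nb_sum = ndimage.convolve(gray.astype(np.float64), kernel, mode="constant")
    valid = mask & (nb_cnt > 0)
    levels = gray[valid]
    diffs = np.abs(levels - nb_sum[valid] / nb_cnt[valid])
    n_i = np.bincount(levels - 1, minlength=ng).astype(np.float64)
    s_i = np.bincount(levels - 1, weights=diffs, minlength=ng)
    total = n_i.sum()
    p_i = n_i / total if total > 0 else n_i
    return n_i, p_i, s_i
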