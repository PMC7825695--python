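"""Independent brute-force oracles for the texture-matrix definitions.

Everything here is written straight from the matrix definitions with
explicit Python loops — deliberately naive, sharing no code with the
package — so the vectorized constructions can be checked against them on
small random volumes.
"""

from __future__ import annotations

import numpy as np

NEIGHBORS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def oracle_glcm(gray: np.ndarray, ng: int, offset: tuple[int, int, int]) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset by pair enumeration."""
    M = np.zeros((ng, ng), dtype=np.int64)
    shape = gray.shape
    for p in np.ndindex(shape):
        if gray[p] == 0:
            continue
        q = tuple(c + o for c, o in zip(p, offset))
        if _inside(shape, q) and gray[q] > 0:
            M[gray[p] - 1, gray[q] - 1] += 1
            M[gray[q] - 1, gray[p] - 1] += 1
    return M


def oracle_glrlm(gray: np.ndarray, ng: int, direction: tuple[int, int, int]) -> np.ndarray:
    """Run-length counts for one direction by explicit line walking."""
    shape = gray.shape
    runs: list[tuple[int, int]] = []
    neg = tuple(-d for d in direction)
    for start in np.ndindex(shape):
        if gray[start] == 0:
            continue
        prev = tuple(c + o for c, o in zip(start, neg))
        # only begin a run where the previous voxel along the line is not
        # part of the same run
        if _inside(shape, prev) and gray[prev] == gray[start]:
            continue
        length = 1
        cur = start
        while True:
            nxt = tuple(c + o for c, o in zip(cur, direction))
            if _inside(shape, nxt) and gray[nxt] == gray[start]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((gray[start], length))
    nr = max(l for _, l in runs)
    P = np.zeros((ng, nr), dtype=np.int64)
    for level, length in runs:
        P[level - 1, length - 1] += 1
    return P


def oracle_zones(gray: np.ndarray, ng: int) -> np.ndarray:
    """Zone sizes by flood fill over 26-connected equal-level components."""
    shape = gray.shape
    seen = np.zeros(shape, dtype=bool)
    sizes: list[tuple[int, int]] = []
    for start in np.ndindex(shape):
        if gray[start] == 0 or seen[start]:
            continue
        level = gray[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            p = stack.pop()
            size += 1
            for off in NEIGHBORS_26:
                q = tuple(c + o for c, o in zip(p, off))
                if _inside(shape, q) and not seen[q] and gray[q] == level:
                    seen[q] = True
                    stack.append(q)
        sizes.append((level, size))
    max_size = max(s for _, s in sizes)
    P = np.zeros((ng, max_size), dtype=np.int64)
    for level, size in sizes:
        P[level - 1, size - 1] += 1
    return P


def oracle_gldm(gray: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence counts by per-voxel neighbour enumeration."""
    shape = gray.shape
    P = np.zeros((ng, 27), dtype=np.int64)
    for p in np.ndindex(shape):
        if gray[p] == 0:
            continue
        d = 0
        for off in NEIGHBORS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inside(shape, q) and gray[q] > 0 and abs(int(gray[q]) - int(gray[p])) <= alpha:
                d += 1
        P[gray[p] - 1, d] += 1
    return P


def oracle_ngtdm(gray: np.ndarray, ng: int):
    """(n_i, s_i) by per-voxel neighbourhood averaging."""
    shape = gray.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for p in np.ndindex(shape):
        if gray[p] == 0:
            continue
        vals = []
        for off in NEIGHBORS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inside(shape, q) and gray[q] > 0:
                vals.append(gray[q])
        if not vals:
            continue
        n_i[gray[p] - 1] += 1
        s_i[gray[p] - 1] += abs(gray[p] - np.mean(vals))
    return n_i, s_i


def oracle_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive concordant-pair counting (ties worth 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def random_gray_volume(rng: np.random.Generator, max_shape=(5, 5, 3), max_ng=4):
    """A random small discretized volume with a random mask (0 outside)."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    ng = int(rng.integers(1, max_ng + 1))
    gray = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < 0.8
    if not mask.any():
        mask.flat[0] = True
    gray = gray * mask
    # make sure the nominal maximum level is present so matrices have Ng rows
    gray[tuple(np.argwhere(mask)[0])] = ng
    return gray.astype(np.int64), ng
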