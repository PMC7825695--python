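"""Texture features computed from the gray-level matrices.

GLCM and GLRLM features are computed per direction and averaged over the
13 directions; GLSZM, GLDM and NGTDM are single-matrix classes.

Degenerate-input conventions (all unit-tested):

* GLCM with a single gray level: correlation = 1, MCC = 1, contrast and
  the other dispersion terms 0 (a constant ROI is perfectly correlated
  with itself).
* Entropies sum ``-p log2 p`` over nonzero cells only.
* GLDM emphasis weights use the dependence *size* ``d + 1`` (the voxel
  itself plus its dependent neighbours) so an isolated voxel (d = 0) does
  not divide by zero; matrix columns remain the raw neighbour counts.
* NGTDM coarseness is capped at 1e6 when ``sum(p_i s_i) = 0`` (perfectly
  homogeneous ROI); busyness and strength return 0 when their denominators
  vanish.
"""

from __future__ import annotations

import numpy as np

COARSENESS_CAP = 1e6


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _glcm_single(counts: np.ndarray) -> dict[str, float]:
    total = counts.sum()
    if total == 0:  # no voxel pairs in this direction: treat as one-level ROI
        counts, total = np.array([[1.0]]), 1.0
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(px * i))
    sigma2 = float(np.sum(px * (i - mu) ** 2))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in range(ng)])
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in range(2, 2 * ng + 1)])

    diff_avg = float(np.sum(p_diff * k_diff))
    hxy = _entropy(p.ravel())
    hx = _entropy(px)
    pxpy = np.outer(px, px)
    nz = pxpy > 0
    log_pxpy = np.zeros_like(pxpy)
    log_pxpy[nz] = np.log2(pxpy[nz])
    hxy1 = float(-np.sum(p[nz] * log_pxpy[nz]))
    hxy2 = float(-np.sum(pxpy[nz] * log_pxpy[nz]))

    if sigma2 > 0:
        correlation = float((np.sum(p * ii * jj) - mu * mu) / sigma2)
    else:
        correlation = 1.0

    if ng > 1 and np.all(px > 0):
        q = (p / px[:, None]) @ (p / px[None, :]).T  # Q(i,j)=sum_k p(i,k)p(j,k)/(px(i)py(k))
        eig = np.sort(np.real(np.linalg.eigvals(q)))[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0))) if len(eig) > 1 else 1.0
    elif ng > 1:
        # rows with zero marginal never co-occur; drop them and recurse
        keep = px > 0
        return _glcm_single(counts[np.ix_(keep, keep)])
    else:
        mcc = 1.0

    imc1 = (hxy - hxy1) / max(hx, 1e-16) if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    return {
        "Autocorrelation": float(np.sum(p * ii * jj)),
        "ClusterProminence": float(np.sum(p * (ii + jj - 2 * mu) ** 4)),
        "ClusterShade": float(np.sum(p * (ii + jj - 2 * mu) ** 3)),
        "ClusterTendency": float(np.sum(p * (ii + jj - 2 * mu) ** 2)),
        "Contrast": float(np.sum(p * (ii - jj) ** 2)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": _entropy(p_diff),
        "DifferenceVariance": float(np.sum(p_diff * (k_diff - diff_avg) ** 2)),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float(np.sum(p[off] / (ii[off] - jj[off]) ** 2)),
        "JointAverage": mu,
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float(np.sum(p_sum * k_sum)),
        "SumEntropy": _entropy(p_sum),
        "SumSquares": sigma2,
    }


def glcm_features(matrices: list[np.ndarray]) -> dict[str, float]:
    """Average the 24 co-occurrence features over the 13 directions."""
    per_dir = [_glcm_single(m) for m in matrices]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# run length / size zone (shared formula core)
# ---------------------------------------------------------------------------

def _rl_core(P: np.ndarray, n_voxels: int, zone: bool) -> dict[str, float]:
    """Features of a (level x size) count matrix.

    With ``zone=False`` sizes are run lengths (GLRLM names); with
    ``zone=True`` they are zone sizes (GLSZM names).
    """
    P = P.astype(np.float64)
    ns = P.sum()
    ng, nl = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    l = np.arange(1, nl + 1, dtype=np.float64)
    ii, ll = np.meshgrid(i, l, indexing="ij")
    p = P / ns
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    mu_i = np.sum(p * ii)
    mu_l = np.sum(p * ll)

    small = float(np.sum(P / ll**2) / ns)
    large = float(np.sum(P * ll**2) / ns)
    low = float(np.sum(P / ii**2) / ns)
    high = float(np.sum(P * ii**2) / ns)
    vals = {
        "GrayLevelNonUniformity": float(np.sum(row**2) / ns),
        "GrayLevelNonUniformityNormalized": float(np.sum(row**2) / ns**2),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
    }
    if zone:
        vals.update(
            {
                "HighGrayLevelZoneEmphasis": high,
                "LargeAreaEmphasis": large,
                "LargeAreaHighGrayLevelEmphasis": float(np.sum(P * ll**2 * ii**2) / ns),
                "LargeAreaLowGrayLevelEmphasis": float(np.sum(P * ll**2 / ii**2) / ns),
                "LowGrayLevelZoneEmphasis": low,
                "SizeZoneNonUniformity": float(np.sum(col**2) / ns),
                "SizeZoneNonUniformityNormalized": float(np.sum(col**2) / ns**2),
                "SmallAreaEmphasis": small,
                "SmallAreaHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ll**2) / ns),
                "SmallAreaLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ll**2)) / ns),
                "ZoneEntropy": _entropy(p.ravel()),
                "ZonePercentage": float(ns / n_voxels),
                "ZoneVariance": float(np.sum(p * (ll - mu_l) ** 2)),
            }
        )
    else:
        vals.update(
            {
                "HighGrayLevelRunEmphasis": high,
                "LongRunEmphasis": large,
                "LongRunHighGrayLevelEmphasis": float(np.sum(P * ll**2 * ii**2) / ns),
                "LongRunLowGrayLevelEmphasis": float(np.sum(P * ll**2 / ii**2) / ns),
                "LowGrayLevelRunEmphasis": low,
                "RunEntropy": _entropy(p.ravel()),
                "RunLengthNonUniformity": float(np.sum(col**2) / ns),
                "RunLengthNonUniformityNormalized": float(np.sum(col**2) / ns**2),
                "RunPercentage": float(ns / n_voxels),
                "RunVariance": float(np.sum(p * (ll - mu_l) ** 2)),
                "ShortRunEmphasis": small,
                "ShortRunHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ll**2) / ns),
                "ShortRunLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ll**2)) / ns),
            }
        )
    return vals


def glrlm_features(matrices: list[np.ndarray], n_voxels: int) -> dict[str, float]:
    """Average the 16 run-length features over the 13 directions."""
    per_dir = [_rl_core(m, n_voxels, zone=False) for m in matrices]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    return _rl_core(P, n_voxels, zone=True)


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_features(P: np.ndarray) -> dict[str, float]:
    P = P.astype(np.float64)
    nz = P.sum()  # == number of ROI voxels
    ng, nd = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    s = np.arange(1, nd + 1, dtype=np.float64)  # dependence size = count + 1
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = P / nz
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    mu_s = np.sum(p * ss)
    return {
        "DependenceEntropy": _entropy(p.ravel()),
        "DependenceNonUniformity": float(np.sum(col**2) / nz),
        "DependenceNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "DependenceVariance": float(np.sum(p * (ss - mu_s) ** 2)),
        "GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "GrayLevelVariance": float(
            np.sum(p * (ii - np.sum(p * ii)) ** 2)
        ),
        "HighGrayLevelEmphasis": float(np.sum(P * ii**2) / nz),
        "LargeDependenceEmphasis": float(np.sum(P * ss**2) / nz),
        "LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * ss**2 * ii**2) / nz),
        "LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * ss**2 / ii**2) / nz),
        "LowGrayLevelEmphasis": float(np.sum(P / ii**2) / nz),
        "SmallDependenceEmphasis": float(np.sum(P / ss**2) / nz),
        "SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * ii**2 / ss**2) / nz),
        "SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (ii**2 * ss**2)) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(
    n_i: np.ndarray, p_i: np.ndarray, s_i: np.ndarray
) -> dict[str, float]:
    ng = len(p_i)
    i = np.arange(1, ng + 1, dtype=np.float64)
    present = p_i > 0
    ngp = int(present.sum())
    n_total = n_i.sum()

    ps = float(np.sum(p_i * s_i))
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1 and n_total > 0:
        ia, ib = np.meshgrid(i[present], i[present], indexing="ij")
        pa, pb = np.meshgrid(p_i[present], p_i[present], indexing="ij")
        sa, sb = np.meshgrid(s_i[present], s_i[present], indexing="ij")
        contrast = float(
            np.sum(pa * pb * (ia - ib) ** 2)
            / (ngp * (ngp - 1))
            * (s_i.sum() / n_total)
        )
        absdiff = float(np.sum(np.abs(ia * pa - ib * pb)))
        busyness = ps / absdiff if absdiff > 0 else 0.0
        complexity = float(
            np.sum(np.abs(ia - ib) * (pa * sa + pb * sb) / (pa + pb)) / n_total
        )
        s_sum = s_i.sum()
        strength = (
            float(np.sum((pa + pb) * (ia - ib) ** 2)) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
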