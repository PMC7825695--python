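"""Derived images: Laplacian-of-Gaussian and undecimated wavelet sub-bands.

The LoG response is the physical-space Laplacian (units mm^-2 x intensity)
of the Gaussian-smoothed volume; sigma is specified in mm and converted to
voxels per axis, so anisotropic grids filter isotropically in space.

The wavelet transform is a single-level undecimated separable 3D
decomposition: each axis is filtered with the analysis low-pass (L) or
high-pass (H) filter of the chosen family, giving the 8 sub-bands
HHH ... LLL, each the same shape as the input.  The n-th letter of a label
applies to array axis n.  Periodic boundary handling makes the filter bank
a tight frame: for an orthonormal family the sub-band energies sum to 8x
the input energy.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pywt
from scipy import ndimage

from ..image import ImageVolume

__all__ = ["apply_log_filter", "wavelet_decompose"]


def _log_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled Gaussian and second-derivative-of-Gaussian 1D kernels.

    The derivative kernel is moment-corrected: exactly zero-sum (no
    response to constants) with discrete second moment 2, so quadratics
    yield their exact Laplacian in the interior.
    """
    radius = max(2, int(4.0 * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    g /= g.sum()
    d2 = (x**2 / sigma**4 - 1.0 / sigma**2) * np.exp(-(x**2) / (2.0 * sigma**2))
    d2 -= d2.mean()
    d2 *= 2.0 / np.sum(d2 * x**2)
    return g, d2


def apply_log_filter(volume: ImageVolume, sigma_mm: float = 5.0) -> ImageVolume:
    """Laplacian-of-Gaussian response with sigma in mm.

    Separable implementation: along each axis the second-derivative kernel
    is applied (divided by the squared spacing so the result is a physical
    Laplacian, mm^-2), with plain Gaussian smoothing along the other two.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma must be > 0")
    kernels = [_log_kernels(sigma_mm / s) for s in volume.spacing]
    out = np.zeros(volume.shape, dtype=np.float64)
    for axis in range(3):
        part = volume.voxels
        for ax2 in range(3):
            k = kernels[ax2][1] if ax2 == axis else kernels[ax2][0]
            part = ndimage.correlate1d(part, k, axis=ax2, mode="nearest")
        out += part / volume.spacing[axis] ** 2
    return volume.with_voxels(out)


def wavelet_decompose(
    volume: ImageVolume, family: str = "coif1"
) -> dict[str, ImageVolume]:
    """Return the 8 undecimated sub-bands keyed 'HHH' ... 'LLL'."""
    wavelet = pywt.Wavelet(family)
    filters = {
        "L": np.asarray(wavelet.dec_lo, dtype=np.float64),
        "H": np.asarray(wavelet.dec_hi, dtype=np.float64),
    }
    flen = len(filters["L"])
    if min(volume.shape) < flen:
        raise ValueError(
            f"volume shape {volume.shape} smaller than the {family} filter "
            f"length {flen} on some axis"
        )
    bands: dict[str, ImageVolume] = {}
    for letters in product("HL", repeat=3):
        arr = volume.voxels
        for axis, letter in enumerate(letters):
            arr = ndimage.correlate1d(arr, filters[letter], axis=axis, mode="wrap")
        bands["".join(letters)] = volume.with_voxels(arr)
    return bands
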