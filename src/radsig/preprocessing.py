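"""Intensity preprocessing applied before feature extraction.

The pipeline order is fixed: bias-field correction, then histogram-matching
normalization against a reference volume, then resampling to an isotropic
grid (2 mm by default).  MRI coils impose a smooth multiplicative intensity
field on T2-weighted images; the default corrector estimates that field by
wide Gaussian smoothing in the log domain and divides it out
(``smooth-divide``).  A full N4 correction can be delegated to SimpleITK
when installed (``delegate-n4``).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .image import ImageVolume, ROIMask

__all__ = ["correct_bias_field", "match_histogram", "resample_volume"]


def correct_bias_field(
    volume: ImageVolume,
    method: str = "smooth-divide",
    sigma_mm: float = 25.0,
    n_iterations: int = 8,
    mask: ROIMask | None = None,
) -> ImageVolume:
    """Remove a smooth multiplicative intensity field.

    ``smooth-divide`` is an iterative homomorphic correction: each pass
    estimates the log-field as a wide Gaussian smooth (``sigma_mm``) of the
    current log image and subtracts it.  One pass only attenuates field
    components whose wavelength is comparable to the smoothing kernel, so
    a few passes (default 8) are run; the residual field shrinks
    geometrically while the anatomy, being high-frequency, is barely
    touched after the first pass.  The result is rescaled so the mean
    intensity (over ``mask`` when given, else the whole volume) is
    preserved.  Intensities must be strictly positive for the log
    transform; shift the volume by an offset first if not.
    """
    v = volume.voxels
    if v.min() <= 0:
        raise ValueError(
            "bias correction works in the log domain and requires strictly "
            "positive intensities; add a constant offset to the volume first"
        )
    if method == "delegate-n4":
        return _n4(volume, mask)
    if method != "smooth-divide":
        raise ValueError(f"unknown bias method {method!r}")

    sigma_vox = [sigma_mm / s for s in volume.spacing]
    log_v = np.log(v)
    for _ in range(max(1, n_iterations)):
        log_v = log_v - ndimage.gaussian_filter(log_v, sigma_vox, mode="reflect")
    corrected = np.exp(log_v)

    sel = mask.voxels if mask is not None else slice(None)
    scale = v[sel].mean() / corrected[sel].mean()
    return volume.with_voxels(corrected * scale)


def _n4(volume: ImageVolume, mask: ROIMask | None) -> ImageVolume:
    try:
        import SimpleITK as sitk
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "method='delegate-n4' requires SimpleITK (pip install radsig[n4])"
        ) from err
    img = sitk.GetImageFromArray(volume.voxels.T.astype(np.float32))
    img.SetSpacing(volume.spacing[::-1])
    args = [img]
    if mask is not None:
        m = sitk.GetImageFromArray(mask.voxels.T.astype(np.uint8))
        m.SetSpacing(volume.spacing[::-1])
        args.append(m)
    out = sitk.N4BiasFieldCorrection(*args)
    corrected = sitk.GetArrayFromImage(out).T.astype(np.float64)
    sel = mask.voxels if mask is not None else slice(None)
    scale = volume.voxels[sel].mean() / corrected[sel].mean()
    return volume.with_voxels(corrected * scale)


def match_histogram(
    volume: ImageVolume, reference: ImageVolume, n_landmarks: int = 64
) -> ImageVolume:
    """Map intensities so quantile landmarks match a reference volume.

    A monotone piecewise-linear map is built through ``n_landmarks`` equally
    spaced quantiles of both volumes; values outside the landmark range are
    extrapolated from the end segments.  The map preserves intensity order.
    """
    if n_landmarks < 2:
        raise ValueError("need at least 2 landmarks")
    ref = reference.voxels
    if ref.max() == ref.min():
        raise ValueError("constant reference volume: quantile map undefined")
    q = np.linspace(0.0, 1.0, n_landmarks)
    src = np.quantile(volume.voxels, q)
    dst = np.quantile(ref, q)
    # Collapse duplicated source landmarks (flat histogram regions) so the
    # interpolation abscissae are strictly increasing.
    keep = np.concatenate(([True], np.diff(src) > 0))
    src, dst = src[keep], dst[keep]
    if len(src) < 2:
        # constant input: map everything to the reference median
        return volume.with_voxels(np.full(volume.shape, np.median(ref)))
    v = volume.voxels
    out = np.interp(v, src, dst)
    # linear extrapolation beyond the outermost landmarks
    lo, hi = v < src[0], v > src[-1]
    if lo.any():
        s = (dst[1] - dst[0]) / (src[1] - src[0])
        out[lo] = dst[0] + s * (v[lo] - src[0])
    if hi.any():
        s = (dst[-1] - dst[-2]) / (src[-1] - src[-2])
        out[hi] = dst[-1] + s * (v[hi] - src[-1])
    return volume.with_voxels(out)


def resample_volume(
    volume: ImageVolume,
    mask: ROIMask,
    target_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
) -> tuple[ImageVolume, ROIMask]:
    """Resample volume and mask onto a grid with the requested spacing.

    The volume is interpolated with a cubic B-spline, the mask with nearest
    neighbour (so it stays strictly binary).  The output grid keeps the
    input origin; its extent never reaches past the input's last voxel
    center, so no extrapolation occurs.  Resampling to the native spacing
    is the identity.
    """
    mask.check_aligned(volume)
    target = tuple(float(t) for t in target_spacing)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")

    shape = volume.shape
    new_shape = tuple(
        int(np.floor((n - 1) * s / t + 1e-9)) + 1
        for n, s, t in zip(shape, volume.spacing, target)
    )
    coords = np.meshgrid(
        *[
            np.arange(m) * t / s
            for m, t, s in zip(new_shape, target, volume.spacing)
        ],
        indexing="ij",
    )
    new_vox = ndimage.map_coordinates(
        volume.voxels, coords, order=3, mode="nearest"
    )
    new_mask = ndimage.map_coordinates(
        mask.voxels.astype(np.uint8), coords, order=0, mode="nearest"
    )
    if not new_mask.any():
        raise ValueError(
            f"mask {mask.name!r} vanished when resampling to spacing {target}"
        )
    return (
        ImageVolume(new_vox, target, volume.origin),
        ROIMask(new_mask, target, volume.origin, name=mask.name),
    )
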