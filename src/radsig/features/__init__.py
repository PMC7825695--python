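"""IBSI-style radiomic feature extraction.

The standard configuration computes 944 named features per ROI:

* 107 on the original image — 14 shape + 18 first-order + 24 GLCM +
  16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM;
* 93 on the Laplacian-of-Gaussian image (shape excluded — ROI geometry
  does not change under intensity filters);
* 93 on each of the 8 undecimated wavelet sub-bands (744 total).

Intensities are discretized with a fixed bin width (default 25) anchored
at the ROI minimum, independently for each derived image.  GLCM and GLRLM
use the 13 unique 3D directions at distance 1 and average features over
directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..image import ImageVolume, ROIMask
from .discretize import discretize
from .filters import apply_log_filter, wavelet_decompose
from .firstorder import compute_first_order
from .matrices import (
    gldm_matrix,
    glcm_matrices,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)
from .registry import WAVELET_SUBBANDS, _fmt_sigma, all_feature_names
from .shape import compute_shape
from .texture import (
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = [
    "ExtractionConfig",
    "extract_all",
    "compute_first_order",
    "compute_shape",
    "apply_log_filter",
    "wavelet_decompose",
    "discretize",
    "all_feature_names",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction parameters.

    ``log_sigma_mm`` defaults to 5 — the LoG kernel scale in mm;
    ``glcm_distance`` is the co-occurrence offset in voxels.  Set
    ``image_types`` to a subset of ``("original", "log", "wavelet")`` to
    extract only some image types.
    """

    bin_width: float = 25.0
    target_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    log_sigma_mm: float = 5.0
    wavelet_family: str = "coif1"
    glcm_distance: int = 1
    gldm_alpha: int = 0
    image_types: tuple[str, ...] = ("original", "log", "wavelet")

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.log_sigma_mm <= 0:
            raise ValueError("log_sigma_mm must be > 0")
        if self.glcm_distance < 1:
            raise ValueError("glcm_distance must be >= 1")
        bad = set(self.image_types) - {"original", "log", "wavelet"}
        if bad:
            raise ValueError(f"unknown image types {sorted(bad)}")

    def feature_names(self) -> list[str]:
        return all_feature_names(self.image_types, self.log_sigma_mm)


def _intensity_features(
    image_type: str,
    volume: ImageVolume,
    mask: ROIMask,
    config: ExtractionConfig,
) -> dict[str, float]:
    """The 93 non-shape features of one (possibly derived) image."""
    out = {
        f"{image_type}_firstorder_{k}": v
        for k, v in compute_first_order(volume, mask, config.bin_width).items()
    }
    gray, ng = discretize(volume, mask, config.bin_width)
    n_vox = mask.n_voxels
    out.update(
        {
            f"{image_type}_glcm_{k}": v
            for k, v in glcm_features(
                glcm_matrices(gray, ng, config.glcm_distance)
            ).items()
        }
    )
    out.update(
        {
            f"{image_type}_glrlm_{k}": v
            for k, v in glrlm_features(glrlm_matrices(gray, ng), n_vox).items()
        }
    )
    out.update(
        {
            f"{image_type}_glszm_{k}": v
            for k, v in glszm_features(glszm_matrix(gray, ng), n_vox).items()
        }
    )
    out.update(
        {
            f"{image_type}_gldm_{k}": v
            for k, v in gldm_features(
                gldm_matrix(gray, ng, config.gldm_alpha)
            ).items()
        }
    )
    out.update(
        {
            f"{image_type}_ngtdm_{k}": v
            for k, v in ngtdm_features(*ngtdm_table(gray, ng)).items()
        }
    )
    return out


def extract_all(
    volume: ImageVolume,
    mask: ROIMask,
    config: ExtractionConfig | None = None,
) -> pd.Series:
    """Extract the full feature vector for one (volume, ROI) pair.

    Inputs are expected preprocessed and resampled; the result is an
    ordered Series whose index follows the frozen registry naming.
    """
    config = config or ExtractionConfig()
    mask.check_aligned(volume)
    values: dict[str, float] = {}
    try:
        if "original" in config.image_types:
            values.update(
                {f"original_shape_{k}": v for k, v in compute_shape(mask).items()}
            )
            values.update(_intensity_features("original", volume, mask, config))
        if "log" in config.image_types:
            log_img = apply_log_filter(volume, config.log_sigma_mm)
            values.update(
                _intensity_features(
                    _fmt_sigma(config.log_sigma_mm), log_img, mask, config
                )
            )
        if "wavelet" in config.image_types:
            bands = wavelet_decompose(volume, config.wavelet_family)
            for band in WAVELET_SUBBANDS:
                values.update(
                    _intensity_features(
                        f"wavelet-{band}", bands[band], mask, config
                    )
                )
    except Exception as err:
        raise RuntimeError(
            f"feature extraction failed for ROI {mask.name!r}: {err}"
        ) from err
    names = config.feature_names()
    return pd.Series([values[n] for n in names], index=names, name=mask.name)
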