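"""Frozen registry of feature names.

Column names of extracted feature tables must be stable across runs and
versions, so the full naming scheme lives here and nowhere else:
``{image-type}_{class}_{feature}`` with image types ``original``,
``log-sigma-<s>mm`` and ``wavelet-HHH`` ... ``wavelet-LLL``.

The standard layout is 944 features per ROI: 107 on the original image
(14 shape + 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM), 93 on the Laplacian-of-Gaussian image and 93 on each of the 8
wavelet sub-bands (shape describes the ROI geometry and is not recomputed
on derived images).
"""

from __future__ import annotations

from itertools import product

SHAPE_FEATURES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_FEATURES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "Percentile10",
    "Percentile90",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

GLCM_FEATURES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

GLSZM_FEATURES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

GLDM_FEATURES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

NGTDM_FEATURES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

TEXTURE_CLASSES = (
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("gldm", GLDM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
)

WAVELET_SUBBANDS = tuple("".join(c) for c in product("HL", repeat=3))


def _fmt_sigma(sigma_mm: float) -> str:
    s = f"{sigma_mm:g}".replace(".", "-")
    return f"log-sigma-{s}mm"


def intensity_feature_names(image_type: str) -> list[str]:
    """The 93 non-shape features computed on one (possibly derived) image."""
    names = [f"{image_type}_firstorder_{f}" for f in FIRSTORDER_FEATURES]
    for cls, feats in TEXTURE_CLASSES:
        names += [f"{image_type}_{cls}_{f}" for f in feats]
    return names


def all_feature_names(
    image_types: tuple[str, ...] = ("original", "log", "wavelet"),
    log_sigma_mm: float = 5.0,
) -> list[str]:
    """Ordered names of the full feature vector for a given configuration.

    The default configuration yields 944 names.
    """
    names: list[str] = []
    if "original" in image_types:
        names += [f"original_shape_{f}" for f in SHAPE_FEATURES]
        names += intensity_feature_names("original")
    if "log" in image_types:
        names += intensity_feature_names(_fmt_sigma(log_sigma_mm))
    if "wavelet" in image_types:
        for band in WAVELET_SUBBANDS:
            names += intensity_feature_names(f"wavelet-{band}")
    return names
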