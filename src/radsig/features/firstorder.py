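"""First-order (intensity histogram) features.

18 statistics of the raw ROI intensities; entropy and uniformity are the
only two that use the discretized histogram (same fixed bin width as the
texture matrices).  Variance, skewness and kurtosis are population moments
(no bias correction); kurtosis is not excess kurtosis.  A zero-variance ROI
yields skewness and kurtosis of 0 by convention.
"""

from __future__ import annotations

import numpy as np

from ..image import ImageVolume, ROIMask
from .discretize import discretize


def compute_first_order(
    volume: ImageVolume, mask: ROIMask, bin_width: float = 25.0
) -> dict[str, float]:
    mask.check_aligned(volume)
    x = volume.voxels[mask.voxels]
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    dev = x - mean
    m2 = np.mean(dev**2)
    p10, p25, p75, p90 = np.percentile(x, [10, 25, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))

    _, ng = discretize(volume, mask, bin_width)
    hist = np.bincount(
        np.floor((x - x.min()) / bin_width).astype(np.int64), minlength=ng
    )
    p = hist[hist > 0] / n

    return {
        "Energy": energy,
        "TotalEnergy": volume.voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": float(np.mean(dev**3) / m2**1.5 if m2 > 0 else 0.0),
        "Kurtosis": float(np.mean(dev**4) / m2**2 if m2 > 0 else 0.0),
        "Variance": float(m2),
        "Uniformity": float(np.sum(p**2)),
    }
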