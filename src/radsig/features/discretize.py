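"""Fixed-bin-width gray-level discretization.

Texture matrices are defined on integer gray levels.  Intensities inside
the ROI are binned with a fixed width ``W`` anchored at the ROI minimum:

    level(x) = floor((x - min_ROI) / W) + 1

so levels start at 1 and the number of levels adapts to the ROI range.  A
fixed width (rather than a fixed level count) keeps a given intensity
contrast worth the same number of levels across patients.  Each derived
image (LoG, wavelet sub-bands) is discretized independently with the same
width.
"""

from __future__ import annotations

import numpy as np

from ..image import ImageVolume, ROIMask


def discretize(
    volume: ImageVolume, mask: ROIMask, bin_width: float
) -> tuple[np.ndarray, int]:
    """Return an integer gray-level volume (0 outside the ROI) and Ng.

    Raises on empty ROI or non-positive bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    mask.check_aligned(volume)
    m = mask.voxels
    vals = volume.voxels[m]
    if vals.size == 0:
        raise ValueError("empty ROI")
    levels = np.floor((vals - vals.min()) / bin_width).astype(np.int64) + 1
    gray = np.zeros(volume.shape, dtype=np.int64)
    gray[m] = levels
    return gray, int(levels.max())
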