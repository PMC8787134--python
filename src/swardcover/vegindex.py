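"""Excess-green / excess-red vegetation-index background estimator.

Classical non-learning comparator for background coverage: on chromatic
coordinates r = R/(R+G+B), g = G/(R+G+B), b = B/(R+G+B) the indices

    ExG = 2g - r - b        ExR = 1.4r - g

separate green vegetation (ExG - ExR > 0) from soil, litter and other
non-vegetation (ExG - ExR <= 0).  The share of pixels at or below the zero
threshold is reported as the estimated background coverage of the plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IndexConfig:
    """ExG - ExR thresholding parameters (standard literature values)."""

    exr_coefficient: float = 1.4
    threshold: float = 0.0  # background if ExG - ExR <= threshold


def exg_exr_index(image: np.ndarray, config: IndexConfig = IndexConfig()) -> np.ndarray:
    """Per-pixel ExG - ExR on chromatic coordinates; (H, W) float array.

    Black pixels (R+G+B = 0) have undefined chromatic coordinates and are
    assigned the threshold value, classifying them as background
    (zero-reflectance pixels are not vegetation).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.size == 0:
        raise ValueError("empty image")
    total = img.sum(axis=2)
    black = total == 0
    safe_total = np.where(black, 1.0, total)
    r = img[..., 0] / safe_total
    g = img[..., 1] / safe_total
    b = img[..., 2] / safe_total
    exg = 2.0 * g - r - b
    exr = config.exr_coefficient * r - g
    diff = exg - exr
    diff[black] = config.threshold
    return diff


def exg_exr_background(image: np.ndarray, config: IndexConfig = IndexConfig()) -> float:
    """Estimated background coverage percent of an RGB image.

    100 x fraction of pixels with ExG - ExR at or below the threshold
    (inclusive: "zero or negative" index values count as background).
    """
    diff = exg_exr_index(image, config)
    return 100.0 * float(np.count_nonzero(diff <= config.threshold)) / diff.size
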