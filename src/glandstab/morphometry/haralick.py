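"""Haralick co-occurrence texture features (26 values).

The ROI is converted to grayscale (luminosity weights), quantized, and a
symmetric unit-offset gray-level co-occurrence matrix averaged over the
four principal directions is built per sliding window. The 13
co-occurrence statistics of each window matrix are aggregated across
windows by mean and standard deviation. Windowing supplies the population
behind the mean/std feature pair; window size, stride and gray levels are
configuration, not fixed by the method.
"""
from __future__ import annotations

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import graycomatrix

from .cooccurrence import STAT_NAMES, cooccurrence_stats

_ANGLES = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]


def quantize(image: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Grayscale conversion and quantization to ``n_gray_levels`` levels."""
    img = np.asarray(image)
    if img.ndim == 3:
        gray = rgb2gray(img)  # float in [0, 1]
    else:
        gray = img.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
    q = np.floor(gray * n_gray_levels).astype(np.uint8)
    return np.clip(q, 0, n_gray_levels - 1)


def window_cooccurrence(window: np.ndarray, n_gray_levels: int) -> np.ndarray:
    """Symmetric distance-1 GLCM summed over the 4 directions."""
    glcm = graycomatrix(
        window, distances=[1], angles=_ANGLES, levels=n_gray_levels,
        symmetric=True, normed=False,
    )
    return glcm[:, :, 0, :].sum(axis=-1).astype(float)


def haralick_features(
    image: np.ndarray,
    window_px: int = 32,
    stride_px: int = 16,
    n_gray_levels: int = 64,
) -> dict[str, float]:
    """All 26 texture features of one ROI image."""
    q = quantize(image, n_gray_levels)
    h, w = q.shape
    win = min(window_px, h, w)
    stride = max(1, stride_px)
    rows = list(range(0, max(h - win, 0) + 1, stride))
    cols = list(range(0, max(w - win, 0) + 1, stride))

    per_window: list[dict[str, float]] = []
    for r in rows:
        for c in cols:
            m = window_cooccurrence(q[r : r + win, c : c + win], n_gray_levels)
            per_window.append(cooccurrence_stats(m))

    out: dict[str, float] = {}
    for stat in STAT_NAMES:
        vals = np.array([s[stat] for s in per_window])
        out[f"Mean {stat}"] = float(vals.mean())
        out[f"Std. deviation {stat}"] = float(vals.std())
    return out
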