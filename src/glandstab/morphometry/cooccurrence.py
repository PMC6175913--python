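"""Thirteen statistics of a gray-level / orientation co-occurrence matrix.

The same statistic set describes both pixel-intensity texture (Haralick
family) and gland-orientation disorder (orientation "tensor" family): the
matrix rows/columns index quantized levels and entry (i, j) counts
co-occurrences of level i with level j. Entropies use base-2 logs with the
0·log 0 = 0 convention, so a one-hot matrix has entropy exactly 0 and
energy exactly 1.
"""
from __future__ import annotations

import numpy as np

#: canonical order of the 13 statistics
STAT_NAMES = [
    "contrast energy",
    "contrast inverse moment",
    "contrast average",
    "contrast variance",
    "contrast entropy",
    "average intensity",
    "intensity variance",
    "intensity entropy",
    "entropy",
    "energy",
    "correlation",
    "information measure 1",
    "information measure 2",
]


def degenerate_stats() -> dict[str, float]:
    """Limit values for an empty matrix (no co-occurring pairs)."""
    out = {name: 0.0 for name in STAT_NAMES}
    out["energy"] = 1.0
    return out


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def cooccurrence_stats(matrix: np.ndarray) -> dict[str, float]:
    """Compute the 13 statistics from a (possibly unnormalized) matrix."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    total = m.sum()
    if total <= 0:
        return degenerate_stats()
    p = m / total
    n = p.shape[0]
    levels = np.arange(n, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sd_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    diff = np.abs(ii - jj)
    # distribution of |i - j| (contrast) and i + j (intensity/sum)
    c = np.zeros(n)
    np.add.at(c, diff.astype(int).ravel(), p.ravel())
    s = np.zeros(2 * n - 1)
    np.add.at(s, (ii + jj).astype(int).ravel(), p.ravel())
    ks = np.arange(n, dtype=float)
    ms = np.arange(2 * n - 1, dtype=float)

    contrast_avg = float(ks @ c)
    intensity_avg = float(ms @ s)

    out: dict[str, float] = {}
    out["contrast energy"] = float((ks**2) @ c)
    out["contrast inverse moment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    out["contrast average"] = contrast_avg
    out["contrast variance"] = float(((ks - contrast_avg) ** 2) @ c)
    out["contrast entropy"] = _entropy(c)
    out["average intensity"] = intensity_avg
    out["intensity variance"] = float(((ms - intensity_avg) ** 2) @ s)
    out["intensity entropy"] = _entropy(s)
    hxy = _entropy(p.ravel())
    out["entropy"] = hxy
    out["energy"] = float((p**2).sum())
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = float(
            ((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y)
        )
    else:
        out["correlation"] = 0.0
    # information measures of correlation
    pxy = np.outer(px, py)
    mask = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxy[mask])).sum())
    hxy2 = _entropy(pxy.ravel())
    hx = _entropy(px)
    hy = _entropy(py)
    denom = max(hx, hy)
    out["information measure 1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["information measure 2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    return out
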