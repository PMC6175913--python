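"""Macenko-style stain normalization.

Pixel optical density is OD = -log10((I + 1) / 256) per channel. Tissue
pixels (OD above a background threshold) are projected onto the plane of
the two dominant OD directions found by SVD; the 1st and 99th percentiles
of the pixel angles in that plane define the hematoxylin and eosin stain
vectors. Color deconvolution against an image's own vectors yields two
per-pixel stain intensities; each stain's intensity distribution is
quantile-matched to a template and the image is recomposed through the
template's stain vectors. Background pixels pass through unmodified.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synthetic import HEMATOXYLIN_OD
from .types import Roi

N_QUANTILES = 256
_QGRID = np.linspace(0.0, 1.0, N_QUANTILES)


def optical_density(image: np.ndarray) -> np.ndarray:
    """Per-channel OD with the +1 offset that avoids log(0)."""
    return -np.log10((np.asarray(image, dtype=float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    return np.clip(np.round(256.0 * np.power(10.0, -od) - 1.0), 0, 255).astype(
        np.uint8
    )


@dataclass
class StainModel:
    """Two unit stain vectors in OD space plus per-stain reference
    intensity quantiles from the image the model was estimated on."""

    stain_vectors: np.ndarray       # (2, 3): row 0 = H, row 1 = E
    quantiles: np.ndarray           # (2, N_QUANTILES) intensity quantiles
    od_background_threshold: float = 0.15

    def __post_init__(self) -> None:
        v = np.asarray(self.stain_vectors, dtype=float)
        if v.shape != (2, 3):
            raise ValueError("stain_vectors must be (2, 3)")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be non-zero")
        v = v / norms[:, None]
        cos = abs(float(v[0] @ v[1]))
        if cos > 1.0 - 1e-6:
            raise ValueError("stain vectors are collinear")
        self.stain_vectors = v

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "stain_vectors": self.stain_vectors.tolist(),
                    "quantiles": self.quantiles.tolist(),
                    "od_background_threshold": self.od_background_threshold,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "StainModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            stain_vectors=np.array(d["stain_vectors"]),
            quantiles=np.array(d["quantiles"]),
            od_background_threshold=d["od_background_threshold"],
        )


def _tissue_mask(od: np.ndarray, beta: float) -> np.ndarray:
    """Tissue = pixels with at least one channel OD above the threshold."""
    return od.max(axis=-1) >= beta


def _concentrations(od_pixels: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Least-squares stain concentrations, clipped to be non-negative."""
    sol, *_ = np.linalg.lstsq(vectors.T, od_pixels.T, rcond=None)
    return np.clip(sol.T, 0.0, None)  # (n, 2)


def estimate_stain_model(
    image: np.ndarray | Roi,
    beta: float = 0.15,
    angle_percentiles: tuple[float, float] = (1.0, 99.0),
) -> StainModel:
    """Estimate the two stain vectors and reference histograms of an image."""
    img = image.image if isinstance(image, Roi) else np.asarray(image)
    od = optical_density(img)
    mask = _tissue_mask(od, beta)
    tissue = od[mask]
    if len(tissue) < 100:
        raise ValueError("insufficient tissue for stain estimation")

    # two dominant OD directions by SVD
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2]  # (2, 3)
    # orient the basis so projections are mostly positive
    for i in range(2):
        if (tissue @ basis[i]).sum() < 0:
            basis[i] = -basis[i]
    proj = tissue @ basis.T  # (n, 2)
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, angle_percentiles)
    v_lo = np.cos(lo) * basis[0] + np.sin(lo) * basis[1]
    v_hi = np.cos(hi) * basis[0] + np.sin(hi) * basis[1]
    vecs = []
    for v in (v_lo, v_hi):
        v = np.abs(v) if (v < 0).all() else v
        vecs.append(v / np.linalg.norm(v))
    href = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    if vecs[1] @ href > vecs[0] @ href:
        vecs = [vecs[1], vecs[0]]
    vectors = np.vstack(vecs)
    if abs(float(vectors[0] @ vectors[1])) > 1.0 - 1e-6:
        raise ValueError(
            "stain vectors are collinear (degenerate angle percentiles)"
        )

    conc = _concentrations(tissue, vectors)
    assigned = conc.argmax(axis=1)
    quantiles = np.empty((2, N_QUANTILES))
    for s in range(2):
        vals = conc[assigned == s, s]
        if len(vals) == 0:
            vals = conc[:, s]
        quantiles[s] = np.quantile(vals, _QGRID)
    return StainModel(
        stain_vectors=vectors, quantiles=quantiles,
        od_background_threshold=beta,
    )


def normalize_image(
    image: np.ndarray | Roi,
    source: StainModel,
    template: StainModel,
) -> np.ndarray | Roi:
    """Map an image's per-stain intensity distributions onto a template's
    and recompose through the template stain vectors. Background pixels
    (below the OD threshold) are carried through unmodified."""
    is_roi = isinstance(image, Roi)
    img = image.image if is_roi else np.asarray(image)
    od = optical_density(img)
    mask = _tissue_mask(od, source.od_background_threshold)
    out = img.copy()
    if mask.any():
        conc = _concentrations(od[mask], source.stain_vectors)
        assigned = conc.argmax(axis=1)
        matched = conc.copy()
        # each pixel belongs to the stain with the higher intensity; only
        # that stain's intensity is histogram-matched, the off-stain
        # component is carried through
        for s in range(2):
            idx = assigned == s
            vals = conc[idx, s]
            if len(vals) == 0:
                continue
            src_q = np.quantile(vals, _QGRID)
            matched[idx, s] = np.interp(vals, src_q, template.quantiles[s])
        od_new = matched @ template.stain_vectors
        out[mask] = od_to_rgb(od_new)
    if is_roi:
        return Roi(
            image=out, microns_per_pixel=image.microns_per_pixel,
            roi_id=image.roi_id, site=image.site,
            patient=image.patient, label=image.label,
        )
    return out


def stain_intensity_histograms(
    image: np.ndarray | Roi, model: StainModel
) -> np.ndarray:
    """Per-stain (2, N_QUANTILES) intensity quantiles of an image under a
    given stain model; used to verify self-normalization."""
    img = image.image if isinstance(image, Roi) else np.asarray(image)
    od = optical_density(img)
    mask = _tissue_mask(od, model.od_background_threshold)
    conc = _concentrations(od[mask], model.stain_vectors)
    assigned = conc.argmax(axis=1)
    out = np.empty((2, N_QUANTILES))
    for s in range(2):
        vals = conc[assigned == s, s]
        if len(vals) == 0:
            vals = conc[:, s]
        out[s] = np.quantile(vals, _QGRID)
    return out
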