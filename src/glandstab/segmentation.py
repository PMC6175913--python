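"""Lumen-based gland segmentation.

Pixels are clustered into four tissue classes (nuclei, cytoplasm, stroma,
lumen) by k-means on a random sample of RGB values, every pixel is then
labelled by its nearest centroid, and glands are grown from connected
lumen components out to the surrounding nuclear ring. Segmentation runs
at an equivalent 5X magnification (4 um/px) and boundaries are reported
in 1.25X (16 um/px) coordinates for feature extraction; both scales come
from the image's microns-per-pixel metadata.

Label-assignment rule (the clustering itself is unlabelled): lumen is the
brightest centroid by mean RGB, nuclei the darkest, and of the remaining
two the more saturated centroid is stroma, the paler one cytoplasm.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation
from shapely.geometry import Polygon
from skimage.measure import find_contours, label as cc_label
from skimage.transform import rescale
from sklearn.cluster import KMeans

from .config import ProjectConfig
from .types import Gland, GlandSet, Roi

LABELS = ("nuclei", "cytoplasm", "stroma", "lumen")


@dataclass
class TissueLabelMap:
    """Per-pixel tissue label plus the RGB centroids that induced it."""

    labels: np.ndarray       # (H, W) int, index into label_names
    centroids: np.ndarray    # (4, 3) RGB centroids, row i = label_names[i]
    label_names: tuple[str, ...] = LABELS

    @property
    def lumen_mask(self) -> np.ndarray:
        return self.labels == self.label_names.index("lumen")

    @property
    def nuclei_mask(self) -> np.ndarray:
        return self.labels == self.label_names.index("nuclei")


def _assign_tissue_labels(centroids: np.ndarray) -> np.ndarray:
    """Order raw k-means centroids as (nuclei, cytoplasm, stroma, lumen)."""
    brightness = centroids.mean(axis=1)
    order = np.argsort(brightness)
    nuclei, lumen = order[0], order[3]
    mid = [order[1], order[2]]
    sat = [centroids[i].max() - centroids[i].min() for i in mid]
    stroma = mid[int(np.argmax(sat))]
    cytoplasm = mid[1 - int(np.argmax(sat))]
    return np.array([nuclei, cytoplasm, stroma, lumen])


def classify_tissue_pixels(
    image: np.ndarray,
    k: int = 4,
    n_samples: int = 10000,
    seed: int = 0,
) -> TissueLabelMap:
    """k-means (k=4) on sampled RGB pixels; label all pixels by nearest
    centroid."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    pixels = img.reshape(-1, 3).astype(float)
    if len(np.unique(pixels, axis=0)) < k:
        raise ValueError("fewer than k distinct colors")
    rng = np.random.default_rng(seed)
    if len(pixels) > n_samples:
        sample = pixels[rng.choice(len(pixels), n_samples, replace=False)]
    else:
        sample = pixels
    km = KMeans(n_clusters=k, n_init=10, random_state=int(seed) % (2**31))
    km.fit(sample)
    raw = km.cluster_centers_
    order = _assign_tissue_labels(raw)
    centroids = raw[order]
    d2 = ((pixels[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1).reshape(img.shape[:2])
    return TissueLabelMap(labels=labels, centroids=centroids)


def _smooth_closed(boundary: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average over boundary vertices."""
    if window <= 1 or len(boundary) <= window:
        return boundary
    kernel = np.ones(window) / window
    out = np.empty_like(boundary)
    for d in range(2):
        padded = np.concatenate(
            [boundary[-(window // 2):, d], boundary[:, d],
             boundary[: window // 2, d]]
        )
        out[:, d] = np.convolve(padded, kernel, mode="valid")[: len(boundary)]
    return out


def _grow_component(
    comp_mask: np.ndarray, nuclei_mask: np.ndarray, max_steps: int = 5
) -> np.ndarray:
    """Dilate a lumen component until the next step would enter the
    nuclear ring, or for at most ``max_steps`` steps."""
    current = comp_mask
    for _ in range(max_steps):
        grown = binary_dilation(current)
        if (grown & nuclei_mask).any():
            break
        current = grown
    return current


def segment_glands(
    label_map: TissueLabelMap,
    min_lumen_area_px: int = 30,
    smoothing_window: int = 5,
    roi_id: str = "roi",
    microns_per_pixel: float = 1.0,
) -> GlandSet:
    """Glands from connected lumen components of a tissue label map."""
    lumen = label_map.lumen_mask
    nuclei = label_map.nuclei_mask
    components = cc_label(lumen, connectivity=2)
    glands: list[Gland] = []
    for comp_id in range(1, components.max() + 1):
        comp = components == comp_id
        if comp.sum() < min_lumen_area_px:
            continue
        grown = _grow_component(comp, nuclei)
        padded = np.pad(grown, 1)
        contours = find_contours(padded.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len) - 1.0  # undo padding
        boundary = np.column_stack([contour[:, 1], contour[:, 0]])  # (x, y)
        boundary = _smooth_closed(boundary, smoothing_window)
        if len(boundary) < 4:
            continue
        poly = Polygon(boundary)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.is_empty or poly.geom_type != "Polygon" or poly.area <= 0:
            continue
        ys, xs = np.nonzero(comp)
        glands.append(
            Gland(
                boundary=boundary,
                centroid=np.array([poly.centroid.x, poly.centroid.y]),
                area_px=float(poly.area),
                lumen_pixels=np.column_stack([xs, ys]),
            )
        )
    return GlandSet(glands, roi_id=roi_id, microns_per_pixel=microns_per_pixel)


def segment_roi(roi: Roi, config: ProjectConfig | None = None,
                seed: int | None = None) -> GlandSet:
    """Full protocol: rescale to the segmentation magnification, classify
    tissue, segment glands, and report boundaries in feature-extraction
    (1.25X-equivalent) coordinates."""
    cfg = config or ProjectConfig()
    seed = cfg.seed if seed is None else seed
    factor = roi.microns_per_pixel / cfg.seg_mpp
    if abs(factor - 1.0) > 1e-9:
        img = rescale(
            roi.image.astype(float) / 255.0, factor, channel_axis=2,
            anti_aliasing=factor < 1.0,
        )
        img = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    else:
        img = roi.image
    label_map = classify_tissue_pixels(
        img, n_samples=cfg.kmeans_samples, seed=seed
    )
    glands = segment_glands(
        label_map,
        min_lumen_area_px=cfg.min_lumen_area_px,
        smoothing_window=cfg.smoothing_window,
        roi_id=roi.roi_id,
        microns_per_pixel=cfg.seg_mpp,
    )
    # report at the feature-extraction scale
    scale = cfg.seg_mpp / cfg.feat_mpp
    rescaled = [
        Gland(
            boundary=g.boundary * scale,
            centroid=g.centroid * scale,
            area_px=g.area_px * scale**2,
            lumen_pixels=g.lumen_pixels,
        )
        for g in glands
    ]
    return GlandSet(rescaled, roi_id=roi.roi_id,
                    microns_per_pixel=cfg.feat_mpp)
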