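"""Core containers shared across the pipeline.

Coordinate conventions: pixel coordinates are 0-based ``(x, y)`` with x
rightward and y downward. Physical scale is carried as microns-per-pixel
(``mpp``) so geometry can be expressed in microns regardless of the
magnification an image was processed at.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Roi:
    """An RGB region of interest with resolution metadata and provenance."""

    image: np.ndarray  # (H, W, 3) uint8
    microns_per_pixel: float
    roi_id: str = "roi"
    site: str | None = None
    patient: str | None = None
    label: str | None = None  # noncancer | cancer | gleason3 | gleason4

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("Roi.image must be an (H, W, 3) array")
        if img.dtype != np.uint8:
            raise ValueError("Roi.image must be uint8")
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        self.image = img


@dataclass
class Gland:
    """A single gland: closed boundary polygon, centroid and lumen pixels.

    ``boundary`` is an (N, 2) float array of (x, y) vertices in pixel
    coordinates of the owning :class:`GlandSet`. ``lumen_pixels`` is an
    (M, 2) integer array of (x, y) lumen pixel coordinates; it may be empty
    (fused / lumenless glands contribute geometry only through absence of
    lumen and are dropped by lumen-based segmentation).
    """

    boundary: np.ndarray
    centroid: np.ndarray
    area_px: float
    lumen_pixels: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (N, 2) array")
        if self.boundary.shape[0] < 3:
            raise ValueError("boundary needs at least 3 vertices")


@dataclass
class GlandSet:
    """All glands of one ROI plus the coordinate scale they live in."""

    glands: list[Gland]
    roi_id: str = "roi"
    microns_per_pixel: float = 1.0

    def __len__(self) -> int:
        return len(self.glands)

    def __iter__(self):
        return iter(self.glands)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) centroid array in pixel coordinates."""
        if not self.glands:
            return np.empty((0, 2))
        return np.array([g.centroid for g in self.glands], dtype=float)

    @property
    def centroids_um(self) -> np.ndarray:
        return self.centroids * self.microns_per_pixel

    def boundaries_um(self) -> list[np.ndarray]:
        return [g.boundary * self.microns_per_pixel for g in self.glands]

    def subset(self, indices) -> "GlandSet":
        return GlandSet(
            [self.glands[i] for i in indices],
            roi_id=self.roi_id,
            microns_per_pixel=self.microns_per_pixel,
        )
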