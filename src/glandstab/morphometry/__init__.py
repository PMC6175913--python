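"""Histomorphometric feature extraction.

Five families computed per ROI, concatenated in fixed manifest order:
global graph (51), gland shape (100), orientation disorder (39),
sub-graph (26) and Haralick texture (26) — 242 features, 216 of them
gland-derived. Gland geometry is evaluated in microns so values are
comparable across image resolutions; the texture family is computed on
the image resampled to the feature-extraction scale (1.25X equivalent,
16 um/px by default).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.transform import rescale

from ..config import ProjectConfig
from ..types import GlandSet, Roi
from .cooccurrence import STAT_NAMES, cooccurrence_stats, degenerate_stats
from .disorder import (
    disorder_features,
    gland_orientation,
    orientation_bin,
    orientation_cooccurrence,
)
from .graph import GraphFeatureError, disorder, global_graph_features
from .haralick import haralick_features
from .manifest import (
    FAMILIES,
    FAMILY_SIZES,
    all_feature_names,
    family_of,
    feature_manifest,
    load_shipped_manifest,
)
from .shape import (
    aggregate_measurements,
    boundary_measurements,
    measurement_matrix,
    shape_features,
)
from .subgraph import SubgraphPartition, build_subgraphs, subgraph_features

__all__ = [
    "STAT_NAMES", "cooccurrence_stats", "degenerate_stats",
    "disorder_features", "gland_orientation", "orientation_bin",
    "orientation_cooccurrence", "GraphFeatureError", "disorder",
    "global_graph_features", "haralick_features", "FAMILIES", "FAMILY_SIZES",
    "all_feature_names", "family_of", "feature_manifest",
    "load_shipped_manifest", "aggregate_measurements",
    "boundary_measurements", "measurement_matrix", "shape_features",
    "SubgraphPartition", "build_subgraphs", "subgraph_features",
    "CachedExtractor", "extract_feature_vector",
]


def _rescale_for_texture(roi: Roi, feat_mpp: float) -> np.ndarray:
    factor = roi.microns_per_pixel / feat_mpp
    if abs(factor - 1.0) < 1e-9:
        return roi.image
    img = rescale(
        roi.image.astype(float) / 255.0, factor, channel_axis=2,
        anti_aliasing=factor < 1.0,
    )
    return np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)


class CachedExtractor:
    """Extracts the 242-feature vector for any subset of an ROI's glands.

    Per-gland quantities (boundary measurements, orientations) and the
    texture family (which depends only on the image) are computed once;
    graph families are recomputed per subset. This makes repeated
    extraction under gland-removal perturbation cheap without changing
    any feature definition.
    """

    def __init__(
        self, roi: Roi | None, glands: GlandSet, config: ProjectConfig | None = None
    ) -> None:
        self.config = config or ProjectConfig()
        self.glands = glands
        if len(glands) == 0:
            raise ValueError("feature extraction requires at least one gland")
        self._shape_matrix = measurement_matrix(glands)
        self._orient_bins = np.array(
            [orientation_bin(gland_orientation(g.boundary)) for g in glands]
        )
        self._centroids_um = glands.centroids_um
        if roi is not None:
            texture_img = _rescale_for_texture(roi, self.config.feat_mpp)
            self._haralick = haralick_features(
                texture_img,
                window_px=self.config.haralick_window_px,
                stride_px=self.config.haralick_stride_px,
                n_gray_levels=self.config.haralick_gray_levels,
            )
        else:
            self._haralick = None

    def vector(self, indices: np.ndarray | None = None) -> pd.Series:
        if indices is None:
            indices = np.arange(len(self.glands))
        indices = np.asarray(indices, dtype=int)
        centroids = self._centroids_um[indices]

        try:
            graph_vals = global_graph_features(centroids)
        except GraphFeatureError as exc:
            raise GraphFeatureError(f"graph family: {exc}") from exc
        shape_vals = aggregate_measurements(self._shape_matrix[indices])

        partition = build_subgraphs(centroids, self.config.subgraph_radius_um)
        per_sub = [
            cooccurrence_stats(
                orientation_cooccurrence(self._orient_bins[indices][comp])
            )
            for comp in partition.components
            if len(comp) >= 2
        ] or [degenerate_stats()]
        disorder_vals: dict[str, float] = {}
        for stat in STAT_NAMES:
            v = np.array([s[stat] for s in per_sub])
            disorder_vals[f"Mean tensor {stat}"] = float(v.mean())
            disorder_vals[f"Std. deviation tensor {stat}"] = float(v.std())
            disorder_vals[f"Range tensor {stat}"] = float(v.max() - v.min())
        subgraph_vals = subgraph_features(partition)

        if self._haralick is None:
            raise ValueError("haralick family: no ROI image was provided")
        merged = {
            **graph_vals, **shape_vals, **disorder_vals, **subgraph_vals,
            **self._haralick,
        }
        names = all_feature_names()
        return pd.Series([merged[n] for n in names], index=names, dtype=float)


def extract_feature_vector(
    roi: Roi | None, glands: GlandSet, config: ProjectConfig | None = None
) -> pd.Series:
    """The full 242-feature vector of one ROI, in manifest order."""
    return CachedExtractor(roi, glands, config).vector()
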