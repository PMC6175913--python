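"""Global architecture features from gland centroids (51 descriptors).

Voronoi-cell, Delaunay and minimum-spanning-tree statistics plus
nearest-neighbor and local-density measurements, all on gland centroid
coordinates in microns. Unbounded Voronoi cells are excluded from polygon
statistics. The "disorder" aggregate of a population x is
1 - 1/(1 + std(x)/mean(x)), a normalized coefficient of variation.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, Voronoi, cKDTree
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPoint, Polygon

from .manifest import graph_feature_names


class GraphFeatureError(ValueError):
    pass


def disorder(values: np.ndarray) -> float:
    """1 - 1/(1 + std/mean); 0 for an empty or zero-mean population."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or v.mean() == 0:
        return 0.0
    return float(1.0 - 1.0 / (1.0 + v.std() / v.mean()))


def _minmax(values: np.ndarray) -> float:
    vmax, vmin = float(values.max()), float(values.min())
    if vmax == vmin:
        return 1.0
    if vmax == 0.0:
        return 0.0
    return vmin / vmax


def _struct_aggs(values: np.ndarray) -> list[float]:
    """average, std. deviation, min/max, disorder — or zeros if empty."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return [0.0, 0.0, 0.0, 0.0]
    return [float(v.mean()), float(v.std()), _minmax(v), disorder(v)]


def _voronoi_stats(vor: Voronoi) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    areas, perims, chords = [], [], []
    bounded_area = 0.0
    for region_idx in vor.point_region:
        region = vor.regions[region_idx]
        if not region or -1 in region:
            continue  # unbounded cell
        verts = vor.vertices[region]
        poly = Polygon(verts)
        if not poly.is_valid or poly.area == 0:
            continue
        areas.append(poly.area)
        perims.append(poly.length)
        bounded_area += poly.area
        if len(verts) >= 2:
            chords.extend(pdist(verts))
    return np.array(areas), np.array(perims), np.array(chords), bounded_area


def global_graph_features(centroids_um: np.ndarray) -> dict[str, float]:
    """All 51 global-graph features from centroid coordinates in microns."""
    pts = np.asarray(centroids_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 4:
        raise GraphFeatureError("insufficient glands for graph features")
    hull = MultiPoint(pts).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise GraphFeatureError(
            "insufficient glands for graph features (collinear centroids)"
        )
    n = len(pts)
    values: list[float] = []

    vor = Voronoi(pts)
    v_area, v_perim, v_chord, bounded_area = _voronoi_stats(vor)
    values += _struct_aggs(v_area)
    values += _struct_aggs(v_perim)
    values += _struct_aggs(v_chord)
    values.append(bounded_area / hull.area)  # Voronoi polygon area coverage

    tri = Delaunay(pts)
    edges = set()
    tri_areas = []
    for simplex in tri.simplices:
        a, b, c = (pts[i] for i in simplex)
        u, v = b - a, c - a
        tri_areas.append(0.5 * abs(u[0] * v[1] - u[1] * v[0]))
        for i in range(3):
            e = tuple(sorted((simplex[i], simplex[(i + 1) % 3])))
            edges.add(e)
    side_lengths = np.array(
        [np.linalg.norm(pts[i] - pts[j]) for i, j in sorted(edges)]
    )
    values += _struct_aggs(side_lengths)
    values += _struct_aggs(np.array(tri_areas))

    dist = squareform(pdist(pts))
    mst = minimum_spanning_tree(dist)
    mst_edges = mst.data[mst.data > 0]
    values += _struct_aggs(mst_edges)

    tree = cKDTree(pts)
    # mean distance to the k nearest neighbors, per gland
    kmax = min(7, n - 1)
    dists, _ = tree.query(pts, k=kmax + 1)
    nn = dists[:, 1:]  # drop self
    for k in (3, 5, 7):
        kk = min(k, kmax)
        per_gland = nn[:, :kk].mean(axis=1)
        values += [
            float(per_gland.mean()),
            float(per_gland.std()),
            disorder(per_gland),
        ]
    for r in (40.0, 60.0, 80.0, 100.0):
        counts = np.array(
            [len(tree.query_ball_point(p, r)) - 1 for p in pts], dtype=float
        )
        values += [float(counts.mean()), float(counts.std()), disorder(counts)]
    nn1 = nn[:, 0]
    values += [float(nn1.mean()), float(nn1.std()), _minmax(nn1), disorder(nn1)]
    values.append(n / (hull.area / 1e6))  # glands per mm^2

    names = graph_feature_names()
    assert len(values) == len(names) == 51
    return dict(zip(names, values))
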