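"""Gland proximity sub-graphs and their 26 local-architecture features.

Glands are connected when their centroids lie within a fixed radius
(default 200 um); sub-graphs are the connected components of that
geometric graph. Path-based quantities (eccentricity, diameter, radius,
path length) use unweighted hop counts and are averaged over connected
pairs / non-singleton components only; singleton conventions are explicit
zeros.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import kurtosis, skew

from .graph import _minmax, disorder
from .manifest import subgraph_feature_names


@dataclass
class SubgraphPartition:
    """Connected components of the gland proximity graph."""

    graph: nx.Graph              # nodes: gland indices; edge attr "length" (um)
    labels: np.ndarray           # (n,) component id per gland
    components: list[list[int]]  # node lists, one per component
    connection_radius_um: float

    @property
    def n_glands(self) -> int:
        return len(self.labels)


def build_subgraphs(
    centroids_um: np.ndarray, connection_radius_um: float
) -> SubgraphPartition:
    """Threshold the centroid distance matrix and extract components."""
    pts = np.asarray(centroids_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("need at least one centroid")
    g = nx.Graph()
    g.add_nodes_from(range(len(pts)))
    if connection_radius_um > 0:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(connection_radius_um):
            g.add_edge(i, j, length=float(np.linalg.norm(pts[i] - pts[j])))
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    labels = np.empty(len(pts), dtype=int)
    for cid, comp in enumerate(components):
        labels[list(comp)] = cid
    return SubgraphPartition(g, labels, components, float(connection_radius_um))


def _moment_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """mean, std, skewness, kurtosis with zero conventions for tiny samples."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 0.0, 0.0, 0.0, 0.0
    sk = float(skew(v)) if v.size > 2 and v.std() > 0 else 0.0
    ku = float(kurtosis(v)) if v.size > 3 and v.std() > 0 else 0.0
    return float(v.mean()), float(v.std()), sk, ku


def _clustering_d(g: nx.Graph) -> float:
    """Mean of the self-inclusive local clustering variant
    D_i = 2(E_i + k_i) / (k_i (k_i + 1)); isolated nodes contribute 0."""
    vals = []
    for node in g.nodes:
        k = g.degree(node)
        if k == 0:
            vals.append(0.0)
            continue
        neigh = list(g.neighbors(node))
        e = sum(1 for a in neigh for b in neigh if a < b and g.has_edge(a, b))
        vals.append(2.0 * (e + k) / (k * (k + 1)))
    return float(np.mean(vals)) if vals else 0.0


def subgraph_features(partition: SubgraphPartition) -> dict[str, float]:
    """All 26 sub-graph features of one ROI."""
    g = partition.graph
    n = partition.n_glands
    comps = partition.components

    edge_lengths = np.array(
        [d["length"] for _, _, d in g.edges(data=True)], dtype=float
    )
    e_mean, e_std, e_skew, e_kurt = _moment_stats(edge_lengths)

    node_ecc: list[float] = [0.0] * n
    comp_diam, comp_rad = [], []
    central_nodes = 0
    path_lengths: list[int] = []
    for comp in comps:
        if len(comp) == 1:
            comp_diam.append(0.0)
            comp_rad.append(0.0)
            continue
        sub = g.subgraph(comp)
        ecc = nx.eccentricity(sub)
        for node, e in ecc.items():
            node_ecc[node] = float(e)
        radius = min(ecc.values())
        comp_diam.append(float(max(ecc.values())))
        comp_rad.append(float(radius))
        central_nodes += sum(1 for e in ecc.values() if e == radius)
        for _, lengths in nx.shortest_path_length(sub):
            path_lengths.extend(v for v in lengths.values() if v > 0)

    node_ecc_arr = np.asarray(node_ecc)
    comp_diam_arr = np.asarray(comp_diam)
    comp_rad_arr = np.asarray(comp_rad)
    sizes = np.array([len(c) for c in comps], dtype=float)
    s_mean, s_std, s_skew, s_kurt = _moment_stats(sizes)

    values = {
        "Mean of edge length": e_mean,
        "Std. deviation of edge length": e_std,
        "Skewness of edge length": e_skew,
        "Kurtosis of edge length": e_kurt,
        "Average eccentricity": float(node_ecc_arr.mean()),
        "Average eccentricity 90th percentile": float(
            np.percentile(node_ecc_arr, 90)
        ),
        "Diameter": float(comp_diam_arr.mean()),
        "Diameter 90th percentile": float(np.percentile(comp_diam_arr, 90)),
        "Radius": float(comp_rad_arr.mean()),
        "Radius 90th percentile": float(np.percentile(comp_rad_arr, 90)),
        "Average path length": (
            float(np.mean(path_lengths)) if path_lengths else 0.0
        ),
        "Clustering coefficient C": float(nx.average_clustering(g)),
        "Clustering coefficient D": _clustering_d(g),
        "Clustering coefficient E": float(nx.transitivity(g)),
        "Giant component ratio": float(sizes.max() / n),
        "Percentage of isolated glands": float((sizes == 1).sum() / n),
        "Number of end nodes": float(
            sum(1 for node in g.nodes if g.degree(node) == 1)
        ),
        "Number of central nodes": float(central_nodes),
        "Number of components": float(len(comps)),
        "Average degree": float(2.0 * g.number_of_edges() / n),
        "Mean component size": s_mean,
        "Std. deviation component size": s_std,
        "Min/max component size": _minmax(sizes),
        "Disorder of component size": disorder(sizes),
        "Skewness of component size": s_skew,
        "Kurtosis of component size": s_kurt,
    }
    assert list(values) == subgraph_feature_names()
    return values
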