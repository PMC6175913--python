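"""Gland orientation disorder features (39 values).

Each gland's orientation is the angle of the first principal axis of its
boundary vertex cloud against the fixed reference direction (1, 0), folded
to [0, 180). Orientations are binned at 10-degree resolution into an
18x18 co-occurrence matrix per sub-graph: entry (i, j) counts how often a
gland of orientation bin i shares a sub-graph with a gland of bin j (all
unordered pairs, counted symmetrically). The 13 co-occurrence statistics
of each matrix are aggregated across sub-graphs by mean, standard
deviation and range.
"""
from __future__ import annotations

import numpy as np

from ..types import GlandSet
from .cooccurrence import STAT_NAMES, cooccurrence_stats, degenerate_stats
from .subgraph import SubgraphPartition

N_BINS = 18
BIN_DEG = 10.0


def gland_orientation(boundary: np.ndarray) -> float:
    """Principal-axis angle of the boundary vertices, in degrees [0, 180).

    Ties between the two principal axes (an isotropic boundary such as a
    circle) resolve deterministically to the lower angle.
    """
    pts = np.asarray(boundary, dtype=float)
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("orientation needs at least 3 distinct points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    if evals[1] <= 0:
        raise ValueError("degenerate boundary: zero spatial variance")
    if evals[0] <= evals[1] * 1e-12:
        raise ValueError("degenerate boundary: collinear points")

    def fold(vec: np.ndarray) -> float:
        ang = np.degrees(np.arctan2(vec[1], vec[0])) % 180.0
        return float(ang if ang < 180.0 - 1e-9 else 0.0)

    rel_gap = (evals[1] - evals[0]) / evals[1]
    if rel_gap < 1e-9:  # isotropic: principal axes tied
        return min(fold(evecs[:, 1]), fold(evecs[:, 0]))
    return fold(evecs[:, 1])


def orientation_bin(angle_deg: float) -> int:
    """10-degree bin index in [0, 17]."""
    b = int(angle_deg // BIN_DEG)
    return min(max(b, 0), N_BINS - 1)


def orientation_cooccurrence(bins: np.ndarray) -> np.ndarray:
    """Symmetric 18x18 matrix over all unordered pairs of one sub-graph."""
    m = np.zeros((N_BINS, N_BINS))
    bins = np.asarray(bins, dtype=int)
    for i in range(len(bins)):
        for j in range(i + 1, len(bins)):
            m[bins[i], bins[j]] += 1
            m[bins[j], bins[i]] += 1
    return m


def disorder_features(
    glands: GlandSet, partition: SubgraphPartition
) -> dict[str, float]:
    """All 39 orientation-disorder features of one ROI."""
    angles = np.array([gland_orientation(g.boundary) for g in glands])
    bins = np.array([orientation_bin(a) for a in angles])

    per_subgraph: list[dict[str, float]] = []
    for comp in partition.components:
        if len(comp) < 2:
            continue
        per_subgraph.append(
            cooccurrence_stats(orientation_cooccurrence(bins[comp]))
        )
    if not per_subgraph:
        per_subgraph = [degenerate_stats()]

    out: dict[str, float] = {}
    for stat in STAT_NAMES:
        vals = np.array([s[stat] for s in per_subgraph])
        out[f"Mean tensor {stat}"] = float(vals.mean())
        out[f"Std. deviation tensor {stat}"] = float(vals.std())
        out[f"Range tensor {stat}"] = float(vals.max() - vals.min())
    return out
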