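"""Canonical 242-feature manifest.

The five families and their cardinalities are fixed: global graph (51),
gland shape (100), orientation disorder (39), sub-graph (26) and Haralick
texture (26) — 216 gland-derived plus 26 texture features. The exact
member list is defined here, in extraction order, and shipped as
``data/feature_manifest.csv`` so downstream tables always agree on names
and ordering.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

from .cooccurrence import STAT_NAMES

FAMILIES = ["graph", "shape", "disorder", "subgraph", "haralick"]
FAMILY_SIZES = {"graph": 51, "shape": 100, "disorder": 39, "subgraph": 26,
                "haralick": 26}

_STRUCT_AGGS = ["average", "std. deviation", "min/max", "disorder"]

#: the 25 per-gland boundary measurements (shape family)
SHAPE_MEASUREMENTS = (
    ["area", "perimeter", "area ratio", "perimeter ratio", "distance ratio",
     "std. deviation of distance", "variance of distance", "smoothness",
     "fractal dimension"]
    + [f"invariant moment {i}" for i in range(1, 8)]
    + [f"Fourier descriptor {i}" for i in range(1, 10)]
)
SHAPE_AGGS = ["Mean", "Median", "Std. deviation", "Min/max"]


def _shape_name(agg: str, measurement: str) -> str:
    # "Std. deviation of std. deviation of distance" (Table-style phrasing)
    if measurement.startswith(("std.", "variance")):
        return f"{agg} of {measurement}"
    return f"{agg} {measurement}"


def shape_feature_names() -> list[str]:
    return [_shape_name(a, m) for m in SHAPE_MEASUREMENTS for a in SHAPE_AGGS]


def graph_feature_names() -> list[str]:
    names: list[str] = []
    for quantity in ["Voronoi area", "Voronoi perimeter", "Voronoi chord"]:
        names += [f"{quantity} {agg}" for agg in _STRUCT_AGGS]
    names.append("Voronoi polygon area")  # bounded-cell coverage fraction
    for quantity in ["Delaunay side length", "Delaunay triangle area"]:
        names += [f"{quantity} {agg}" for agg in _STRUCT_AGGS]
    names += [f"MST edge length {agg}" for agg in _STRUCT_AGGS]
    for k in (3, 5, 7):
        names += [
            f"Mean distance to {k} nearest neighbors",
            f"Std. deviation distance to {k} nearest neighbors",
            f"Disorder of distance to {k} nearest neighbors",
        ]
    for r in (40, 60, 80, 100):
        names += [
            f"Mean neighbors in {r} micron radius",
            f"Std. deviation neighbors in {r} micron radius",
            f"Disorder of neighbors in {r} micron radius",
        ]
    names += [
        "Mean distance to nearest neighbor",
        "Std. deviation distance to nearest neighbor",
        "Min/max distance to nearest neighbor",
        "Disorder of distance to nearest neighbor",
        "Gland density",
    ]
    return names


def subgraph_feature_names() -> list[str]:
    return [
        "Mean of edge length",
        "Std. deviation of edge length",
        "Skewness of edge length",
        "Kurtosis of edge length",
        "Average eccentricity",
        "Average eccentricity 90th percentile",
        "Diameter",
        "Diameter 90th percentile",
        "Radius",
        "Radius 90th percentile",
        "Average path length",
        "Clustering coefficient C",
        "Clustering coefficient D",
        "Clustering coefficient E",
        "Giant component ratio",
        "Percentage of isolated glands",
        "Number of end nodes",
        "Number of central nodes",
        "Number of components",
        "Average degree",
        "Mean component size",
        "Std. deviation component size",
        "Min/max component size",
        "Disorder of component size",
        "Skewness of component size",
        "Kurtosis of component size",
    ]


def disorder_feature_names() -> list[str]:
    names = []
    for stat in STAT_NAMES:
        for agg in ("Mean", "Std. deviation", "Range"):
            names.append(f"{agg} tensor {stat}")
    return names


def haralick_feature_names() -> list[str]:
    names = []
    for stat in STAT_NAMES:
        for agg in ("Mean", "Std. deviation"):
            names.append(f"{agg} {stat}")
    return names


_FAMILY_BUILDERS = {
    "graph": graph_feature_names,
    "shape": shape_feature_names,
    "disorder": disorder_feature_names,
    "subgraph": subgraph_feature_names,
    "haralick": haralick_feature_names,
}


def feature_manifest() -> pd.DataFrame:
    """Full ordered manifest: columns name, family, index."""
    rows = []
    for family in FAMILIES:
        for name in _FAMILY_BUILDERS[family]():
            rows.append({"name": name, "family": family})
    df = pd.DataFrame(rows)
    df["index"] = range(len(df))
    if df["name"].duplicated().any():
        raise AssertionError("feature names must be globally unique")
    for family, size in FAMILY_SIZES.items():
        got = int((df["family"] == family).sum())
        if got != size:
            raise AssertionError(f"{family}: {got} features, expected {size}")
    return df


def all_feature_names() -> list[str]:
    return feature_manifest()["name"].tolist()


def family_of() -> dict[str, str]:
    df = feature_manifest()
    return dict(zip(df["name"], df["family"]))


def load_shipped_manifest() -> pd.DataFrame:
    """Read the manifest CSV bundled with the package."""
    ref = importlib.resources.files("glandstab") / "data" / "feature_manifest.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
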