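"""Readers and writers for feature tables, gland sidecars and images.

Feature tables are CSV with a mandatory header: metadata columns
``region_id, patient_id, site, class`` followed by numeric feature
columns. Files written by this package carry a leading ``#`` comment line
embedding the package version and config snapshot; readers skip comment
lines. Gland sets are stored as a JSON sidecar with polygons as ordered
(x, y) pixel vertex lists (0-based, x rightward, y downward).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .config import ProjectConfig
from .types import Gland, GlandSet, Roi

META_COLS = ["region_id", "patient_id", "site", "class"]


def feature_columns_of(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLS]


def split_table(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(metadata, features) views of a feature table."""
    feats = feature_columns_of(table)
    return table[META_COLS], table[feats]


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV, validating metadata and numeric cells."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    for col in META_COLS:
        if col not in df.columns:
            raise ValueError(f"feature table is missing column {col!r}")
    out = df[META_COLS].copy()
    for col in df.columns:
        if col in META_COLS:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row}"
            )
        out[col] = converted
    return out


def write_feature_table(
    table: pd.DataFrame, path, config: ProjectConfig | None = None
) -> None:
    path = Path(path)
    snapshot = (config or ProjectConfig()).snapshot()
    with open(path, "w") as fh:
        fh.write(f"# {snapshot}\n")
        table.to_csv(fh, index=False)


def write_gland_set(glands: GlandSet, path) -> None:
    payload = {
        "roi_id": glands.roi_id,
        "microns_per_pixel": glands.microns_per_pixel,
        "glands": [
            {
                "boundary": np.asarray(g.boundary).tolist(),
                "centroid": np.asarray(g.centroid).tolist(),
                "area_px": g.area_px,
            }
            for g in glands
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_gland_set(path) -> GlandSet:
    with open(path) as fh:
        d = json.load(fh)
    glands = [
        Gland(
            boundary=np.array(g["boundary"], dtype=float),
            centroid=np.array(g["centroid"], dtype=float),
            area_px=float(g["area_px"]),
        )
        for g in d["glands"]
    ]
    return GlandSet(glands, roi_id=d["roi_id"],
                    microns_per_pixel=float(d["microns_per_pixel"]))


def write_image(roi: Roi, path) -> None:
    Image.fromarray(roi.image).save(path)


def read_image(path, microns_per_pixel: float, **meta) -> Roi:
    img = np.asarray(Image.open(path).convert("RGB"))
    return Roi(
        image=img, microns_per_pixel=microns_per_pixel,
        roi_id=meta.pop("roi_id", Path(path).stem), **meta,
    )
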