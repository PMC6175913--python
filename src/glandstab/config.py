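"""Flat project configuration.

One document holds every tunable default used across the pipeline so that
an analysis is reproducible from a config file plus a seed. Unknown keys
are rejected rather than silently ignored.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml


@dataclass
class ProjectConfig:
    # statistics
    alpha: float = 0.05              # rank-sum significance level for PI/LI
    pi_threshold: float = 0.25       # stability gate: keep PI < threshold
    top_k: int = 5                   # features retained by every selector
    pi_auc_cv_iterations: int = 100  # per-feature AUC: iterations of k-fold CV
    pi_auc_cv_folds: int = 3
    sfs_cv_iterations: int = 10      # SFS objective: iterations of k-fold CV
    sfs_cv_folds: int = 3
    # morphometry
    subgraph_radius_um: float = 200.0
    haralick_window_px: int = 32
    haralick_stride_px: int = 16
    haralick_gray_levels: int = 64
    # magnification protocol: segment at 5X (4 um/px), extract at 1.25X (16 um/px)
    seg_mpp: float = 4.0
    feat_mpp: float = 16.0
    # segmentation
    min_lumen_area_px: int = 30      # at seg_mpp scale
    smoothing_window: int = 5        # boundary moving-average window (vertices)
    kmeans_samples: int = 10000
    # normalization
    od_background_threshold: float = 0.15
    # randomness
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ProjectConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "ProjectConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key: value mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self) -> str:
        """Compact JSON snapshot embedded in output artifacts."""
        from . import __version__

        return json.dumps(
            {"glandstab": __version__, "config": self.to_dict()},
            sort_keys=True, separators=(",", ":"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
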