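"""Feature instability statistics and the PI-AUC map.

Preparation-induced instability (PI) of a feature is the rate at which
its distribution differs significantly between sites' non-cancerous
regions (two-sided Wilcoxon rank-sum). In exact mode every unordered site
pair is tested once, so PI is a multiple of 1/C(m, 2) for m sites; in
subsampled mode regions are repeatedly subsampled per site and PI is the
rejection fraction over (pair, repetition). Latent instability (LI) is
the within-site baseline: the rejection rate over random half-splits of a
single site's regions.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums

from ._discriminant import cv_auc_per_feature
from .config import ProjectConfig
from .io import feature_columns_of, split_table
from .morphometry import CachedExtractor
from .types import GlandSet, Roi


@dataclass
class InstabilityProfile:
    """Per-feature PI values plus the protocol that produced them."""

    pi: pd.Series                 # feature name -> PI in [0, 1]
    protocol: dict = field(default_factory=dict)
    sites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if ((self.pi < 0) | (self.pi > 1)).any():
            raise ValueError("PI values must lie in [0, 1]")


def _check_sites(table: pd.DataFrame, min_regions: int = 4) -> list[str]:
    sites = sorted(table["site"].unique())
    if len(sites) < 2:
        raise ValueError("instability needs at least 2 sites")
    for site in sites:
        n = int((table["site"] == site).sum())
        if n < min_regions:
            raise ValueError(
                f"site {site!r} has only {n} regions (minimum {min_regions})"
            )
    return sites


def preparation_instability(
    table: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "exact",
    repetitions: int = 100,
    subsample_size: int | None = None,
    seed: int = 0,
) -> InstabilityProfile:
    """PI per feature over the regions in ``table`` (callers restrict to
    non-cancerous regions; the statistic itself is class-agnostic)."""
    if mode not in ("exact", "subsampled"):
        raise ValueError("mode must be 'exact' or 'subsampled'")
    sites = _check_sites(table)
    features = feature_columns_of(table)
    values = {s: table.loc[table["site"] == s, features].to_numpy()
              for s in sites}
    pairs = list(itertools.combinations(sites, 2))
    rng = np.random.default_rng(seed)

    if mode == "exact":
        draws = [values]
    else:
        if subsample_size is None:
            raise ValueError("subsampled mode requires subsample_size")
        draws = []
        for _ in range(repetitions):
            draws.append({
                s: v[rng.choice(len(v), size=min(subsample_size, len(v)),
                                replace=False)]
                for s, v in values.items()
            })

    rejections = np.zeros(len(features))
    n_tests = 0
    for draw in draws:
        for a, b in pairs:
            _, p = ranksums(draw[a], draw[b], axis=0)
            rejections += (p < alpha).astype(float)
            n_tests += 1
    pi = pd.Series(rejections / n_tests, index=features, name="PI")
    return InstabilityProfile(
        pi=pi,
        protocol={
            "mode": mode, "alpha": alpha,
            "repetitions": repetitions if mode == "subsampled" else 1,
            "subsample_size": subsample_size, "seed": seed,
        },
        sites=sites,
    )


def latent_instability(
    table: pd.DataFrame,
    repetitions: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """LI per feature: rejection rate over random half-splits of one site."""
    if table["site"].nunique() != 1:
        raise ValueError("latent instability is defined for a single site")
    features = feature_columns_of(table)
    x = table[features].to_numpy()
    n = len(x)
    if n < 8:
        raise ValueError(f"need at least 8 regions, got {n}")
    rng = np.random.default_rng(seed)
    half = n // 2
    rejections = np.zeros(len(features))
    for _ in range(repetitions):
        perm = rng.permutation(n)
        _, p = ranksums(x[perm[:half]], x[perm[half:]], axis=0)
        rejections += (p < alpha).astype(float)
    return pd.Series(rejections / repetitions, index=features, name="LI")


@dataclass
class PerturbationResult:
    """Mean signed percent change per feature at each gland-removal level."""

    percent_change: pd.DataFrame   # (levels, features); NaN where undefined
    levels_pct: np.ndarray
    sims_per_level: int


def gland_removal_perturbation(
    roi: Roi | None,
    glands: GlandSet,
    config: ProjectConfig | None = None,
    max_removal_pct: int = 20,
    step_pct: int = 1,
    sims_per_level: int = 10,
    seed: int = 0,
    feature_fn=None,
) -> PerturbationResult:
    """Remove 0..max_removal_pct% of glands in step_pct steps, recomputing
    features ``sims_per_level`` times per level.

    Percent change is signed, 100 * (f - f0) / f0, with an absolute-change
    fallback where the unperturbed value is zero. Features undefined after
    removal (too few glands for a family) are NaN, never fabricated.
    ``feature_fn(indices) -> Series`` may replace the built-in extractor.
    """
    n = len(glands)
    if n < 10:
        raise ValueError("perturbation experiment needs at least 10 glands")
    if feature_fn is None:
        extractor = CachedExtractor(roi, glands, config)
        feature_fn = extractor.vector
    base = feature_fn(np.arange(n))
    rng = np.random.default_rng(seed)
    levels = np.arange(0, max_removal_pct + 1, step_pct)

    rows = []
    for level in levels:
        n_remove = int(round(level / 100.0 * n))
        changes = []
        for _ in range(sims_per_level):
            keep = np.arange(n)
            if n_remove > 0:
                removed = rng.choice(n, size=n_remove, replace=False)
                keep = np.setdiff1d(keep, removed)
            try:
                vec = feature_fn(keep)
            except ValueError:  # family undefined after removal
                changes.append(pd.Series(np.nan, index=base.index))
                continue
            delta = vec - base
            with np.errstate(divide="ignore", invalid="ignore"):
                pct = 100.0 * delta / base
            pct = pct.where(base != 0, delta)  # absolute fallback at f0 = 0
            changes.append(pct)
        rows.append(pd.concat(changes, axis=1).mean(axis=1))
    percent_change = pd.DataFrame(rows, index=levels)
    return PerturbationResult(
        percent_change=percent_change,
        levels_pct=levels,
        sims_per_level=sims_per_level,
    )


@dataclass
class PiAucPoint:
    feature: str
    pi: float
    mean_auc: float
    per_site_auc: dict[str, float]


def pi_auc_map(
    table: pd.DataFrame,
    task_classes: tuple[str, str] = ("noncancer", "cancer"),
    noncancer_class: str = "noncancer",
    cv_iterations: int = 100,
    folds: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[PiAucPoint]:
    """Per-feature (PI, mean single-feature LDA CV-AUC) map.

    AUC is computed per site with repeated stratified k-fold CV of a
    single-feature LDA, then averaged across sites; PI comes from the
    non-cancerous regions of the same table.
    """
    features = feature_columns_of(table)
    sites = sorted(table["site"].unique())
    neg, pos = task_classes
    per_site: dict[str, np.ndarray] = {}
    for i, site in enumerate(sites):
        sub = table[(table["site"] == site)
                    & (table["class"].isin(task_classes))]
        y = (sub["class"] == pos).to_numpy()
        if y.all() or not y.any():
            raise ValueError(f"site {site!r} lacks one of the task classes")
        per_site[site] = cv_auc_per_feature(
            sub[features].to_numpy(), y,
            iterations=cv_iterations, folds=folds, seed=seed + i,
        )
    mean_auc = np.mean([per_site[s] for s in sites], axis=0)
    nc = table[table["class"] == noncancer_class]
    profile = preparation_instability(nc, alpha=alpha, mode="exact")
    return [
        PiAucPoint(
            feature=f,
            pi=float(profile.pi[f]),
            mean_auc=float(mean_auc[j]),
            per_site_auc={s: float(per_site[s][j]) for s in sites},
        )
        for j, f in enumerate(features)
    ]
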