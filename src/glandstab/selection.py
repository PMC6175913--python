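"""Feature selectors and the stability gate.

Four selectors, all returning the top-k features (default 5):

* ``sfs`` — sequential forward selection; greedy additions maximizing the
  mean AUC of a QDA over repeated stratified 3-fold CV of the growing set.
* ``wlcx`` — Wilcoxon rank-sum; features ranked by |z| of the rank-sum
  statistic (the class-size-corrected form of "largest difference in the
  sum of ranks").
* ``mrmr`` — minimum redundancy maximum relevance (MID form) on
  quartile-discretized features.
* ``roc`` — top features by orientation-corrected empirical AUC,
  max(AUC, 1 - AUC).

The stability gate precedes any selector in the stability-informed
variant (FS_sd): only features with PI strictly below the threshold
(default 0.25) remain candidates. Ties in every selector break by
canonical feature order; all selectors are deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums
from sklearn.metrics import mutual_info_score

from ._discriminant import cv_auc, empirical_auc_scores
from .stability import InstabilityProfile

SELECTORS = ("sfs", "wlcx", "mrmr", "roc")


class GateError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Ordered selected features plus the selector's per-feature scores."""

    features: list[str]
    selector: str
    gated: bool = False
    pi_threshold: float | None = None
    scores: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("selected features must be distinct")


def stability_gate(
    candidates: list[str],
    profile: InstabilityProfile,
    threshold: float = 0.25,
) -> list[str]:
    """Candidates with PI strictly below the threshold, order preserved."""
    missing = [f for f in candidates if f not in profile.pi.index]
    if missing:
        raise ValueError(f"no PI value for features: {missing[:5]}")
    survivors = [f for f in candidates if profile.pi[f] < threshold]
    if not survivors:
        raise GateError("no features pass the stability gate")
    return survivors


def empirical_auc(values, labels) -> float:
    """Area under the empirical ROC swept over feature-value thresholds;
    orientation as-given, ties contribute one half."""
    return empirical_auc_scores(np.asarray(values, dtype=float),
                                np.asarray(labels, dtype=bool))


def _wlcx_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    stat, _ = ranksums(x[y], x[~y], axis=0)
    return np.abs(np.nan_to_num(stat))


def _roc_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ranks = rankdata(x, axis=0)
    n1 = int(y.sum())
    n0 = len(y) - n1
    auc = (ranks[y].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n0 * n1)
    return np.maximum(auc, 1.0 - auc)


def _discretize(col: np.ndarray, bins: int = 4) -> np.ndarray:
    edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.digitize(col, edges)


def _mrmr_order(x: np.ndarray, y: np.ndarray, k: int) -> tuple[list[int], np.ndarray]:
    n_feat = x.shape[1]
    disc = np.column_stack([_discretize(x[:, j]) for j in range(n_feat)])
    yi = y.astype(int)
    relevance = np.array(
        [mutual_info_score(disc[:, j], yi) for j in range(n_feat)]
    )
    selected: list[int] = []
    remaining = list(range(n_feat))
    mi_cache: dict[tuple[int, int], float] = {}

    def mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(disc[:, a], disc[:, b])
        return mi_cache[key]

    while remaining and len(selected) < k:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if selected:
                redundancy = np.mean([mi(j, s) for s in selected])
            else:
                redundancy = 0.0
            score = relevance[j] - redundancy
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected, relevance


def select_features(
    x: pd.DataFrame,
    y: np.ndarray,
    selector: str,
    k: int = 5,
    seed: int = 0,
    cv_iterations: int = 10,
    cv_folds: int = 3,
) -> SelectionResult:
    """Run one selector over the candidate columns of ``x``.

    ``x`` holds training rows only; its column set defines the candidates
    (pre-gated by the caller for the stability-informed variant).
    """
    selector = selector.lower()
    if selector not in SELECTORS:
        raise ValueError(f"unknown selector {selector!r}")
    y = np.asarray(y, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    if x.shape[1] < k:
        raise ValueError(f"need at least {k} candidate features")
    cols = list(x.columns)
    xv = x.to_numpy(dtype=float)

    if selector in ("wlcx", "roc"):
        scores = (_wlcx_scores if selector == "wlcx" else _roc_scores)(xv, y)
        # stable sort: descending score, ties by canonical column order
        order = np.lexsort((np.arange(len(cols)), -scores))
        chosen = [cols[j] for j in order[:k]]
        score_map = dict(zip(cols, map(float, scores)))
    elif selector == "mrmr":
        idx, relevance = _mrmr_order(xv, y, k)
        chosen = [cols[j] for j in idx]
        score_map = dict(zip(cols, map(float, relevance)))
    else:  # sfs
        selected: list[int] = []
        score_map = {}
        while len(selected) < k:
            best_j, best_auc = None, -np.inf
            for j in range(len(cols)):
                if j in selected:
                    continue
                auc = cv_auc(
                    xv[:, selected + [j]], y,
                    iterations=cv_iterations, folds=cv_folds,
                    seed=seed, shared=False,
                )
                if auc > best_auc + 1e-12:
                    best_j, best_auc = j, auc
            selected.append(best_j)
            score_map[cols[best_j]] = float(best_auc)
        chosen = [cols[j] for j in selected]

    return SelectionResult(
        features=chosen, selector=selector, scores=score_map, seed=seed
    )
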