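"""Classifier wrappers and the hold-one-site-out experiment.

Each fold holds one site out: feature instability (PI) is computed from
the non-cancerous regions of the training sites only, the optional
stability gate and a selector pick the top-k features from training rows
only, a classifier (LDA, QDA, linear SVM or random forest) is trained on
those rows and scored on the held-out site's task regions. Nothing from
the held-out site enters PI, gating, selection or training — mutating
held-out rows must not change any fold's selected features.

Features are standardized with training-split mean/variance before
LDA/QDA/SVM fits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

from ._discriminant import empirical_auc_scores
from .config import ProjectConfig
from .io import feature_columns_of
from .selection import SelectionResult, select_features, stability_gate
from .stability import InstabilityProfile, preparation_instability

CLASSIFIERS = ("lda", "qda", "svm", "rf")
TASKS = {
    "cancer": ("noncancer", "cancer"),
    "gleason": ("gleason3", "gleason4"),
}


def fit_predict_scores(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    classifier: str,
    seed: int = 0,
) -> np.ndarray:
    """Train one of the four classifiers; return continuous scores for the
    test rows, oriented toward the positive class."""
    classifier = classifier.lower()
    if classifier not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}")
    x_train = np.asarray(x_train, dtype=float)
    x_test = np.asarray(x_test, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data must contain both classes")

    if classifier in ("lda", "qda", "svm"):
        mu = x_train.mean(axis=0)
        sd = x_train.std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_train - mu) / sd
        x_test = (x_test - mu) / sd

    if classifier == "lda":
        model = LinearDiscriminantAnalysis()
        model.fit(x_train, y_train)
        return model.decision_function(x_test)
    if classifier == "qda":
        model = QuadraticDiscriminantAnalysis(reg_param=1e-3)
        model.fit(x_train, y_train)
        proba = model.predict_proba(x_test)[:, 1]
        return proba
    if classifier == "svm":
        model = SVC(kernel="linear", C=1.0, random_state=int(seed) % (2**31))
        model.fit(x_train, y_train)
        return model.decision_function(x_test)
    model = RandomForestClassifier(
        n_estimators=100, random_state=int(seed) % (2**31)
    )
    model.fit(x_train, y_train)
    return model.predict_proba(x_test)[:, 1]


@dataclass
class FoldRecord:
    held_out_site: str
    selector: str
    classifier: str
    gated: bool
    auc: float
    selected_features: list[str]


@dataclass
class EvaluationReport:
    """Per-fold hold-one-site-out results for one (selector, classifier,
    gated) combination."""

    task: str
    selector: str
    classifier: str
    gated: bool
    folds: list[FoldRecord]
    mean_auc: float
    std_auc: float
    config_snapshot: str = ""
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "task": self.task,
                    "held_out_site": f.held_out_site,
                    "selector": f.selector,
                    "classifier": f.classifier,
                    "gated": f.gated,
                    "auc": f.auc,
                    "selected_features": "|".join(f.selected_features),
                }
                for f in self.folds
            ]
        )


def _fold_selection(
    table: pd.DataFrame,
    train_sites: list[str],
    task_classes: tuple[str, str],
    selector: str,
    gated: bool,
    k: int,
    pi_threshold: float,
    alpha: float,
    noncancer_class: str,
    seed: int,
    cv_iterations: int,
    cv_folds: int,
) -> tuple[SelectionResult, InstabilityProfile]:
    train = table[table["site"].isin(train_sites)]
    nc = train[train["class"] == noncancer_class]
    profile = preparation_instability(nc, alpha=alpha, mode="exact")
    candidates = feature_columns_of(table)
    if gated:
        candidates = stability_gate(candidates, profile, pi_threshold)
    task_rows = train[train["class"].isin(task_classes)]
    y = (task_rows["class"] == task_classes[1]).to_numpy()
    result = select_features(
        task_rows[candidates], y, selector, k=k, seed=seed,
        cv_iterations=cv_iterations, cv_folds=cv_folds,
    )
    result.gated = gated
    result.pi_threshold = pi_threshold if gated else None
    return result, profile


def hold_one_site_out(
    table: pd.DataFrame,
    task: str,
    selector: str,
    classifier: str,
    gated: bool,
    k: int = 5,
    pi_threshold: float = 0.25,
    alpha: float = 0.05,
    noncancer_class: str = "noncancer",
    seed: int = 0,
    config: ProjectConfig | None = None,
) -> EvaluationReport:
    """One fold per site; selection and PI never see the held-out site."""
    cfg = config or ProjectConfig()
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    task_classes = TASKS[task]
    sites = sorted(table["site"].unique())
    if len(sites) < 3:
        raise ValueError("hold-one-site-out needs at least 3 sites")

    folds: list[FoldRecord] = []
    for held_out in sites:
        train_sites = [s for s in sites if s != held_out]
        result, _ = _fold_selection(
            table, train_sites, task_classes, selector, gated, k,
            pi_threshold, alpha, noncancer_class, seed,
            cfg.sfs_cv_iterations, cfg.sfs_cv_folds,
        )
        train = table[table["site"].isin(train_sites)
                      & table["class"].isin(task_classes)]
        test = table[(table["site"] == held_out)
                     & table["class"].isin(task_classes)]
        y_train = (train["class"] == task_classes[1]).to_numpy()
        y_test = (test["class"] == task_classes[1]).to_numpy()
        if y_test.all() or not y_test.any():
            raise ValueError(f"site {held_out!r} lacks a task class")
        scores = fit_predict_scores(
            train[result.features].to_numpy(), y_train,
            test[result.features].to_numpy(), classifier, seed=seed,
        )
        folds.append(
            FoldRecord(
                held_out_site=held_out,
                selector=selector,
                classifier=classifier,
                gated=gated,
                auc=empirical_auc_scores(scores, y_test),
                selected_features=list(result.features),
            )
        )
    aucs = np.array([f.auc for f in folds])
    return EvaluationReport(
        task=task, selector=selector, classifier=classifier, gated=gated,
        folds=folds, mean_auc=float(aucs.mean()), std_auc=float(aucs.std()),
        config_snapshot=cfg.snapshot(), seed=seed,
    )


def percent_improvement(auc_sd: float, auc_d: float) -> float:
    """100 * (AUC_sd - AUC_d) / AUC_d; positive iff the gated variant wins.
    Computed from unrounded AUCs."""
    if auc_d <= 0:
        raise ValueError("ungated AUC must be positive")
    return 100.0 * (auc_sd - auc_d) / auc_d


def evaluate_grid(
    table: pd.DataFrame,
    task: str,
    selectors=("sfs", "wlcx", "mrmr", "roc"),
    classifiers=("lda", "qda", "svm", "rf"),
    k: int = 5,
    pi_threshold: float = 0.25,
    alpha: float = 0.05,
    seed: int = 0,
    config: ProjectConfig | None = None,
) -> pd.DataFrame:
    """Full selector x classifier grid, gated (FS_sd) and ungated (FS_d),
    with percent improvement per cell. Selection is shared across
    classifiers within a (selector, gated, fold) cell."""
    cfg = config or ProjectConfig()
    task_classes = TASKS[task]
    sites = sorted(table["site"].unique())
    if len(sites) < 3:
        raise ValueError("hold-one-site-out needs at least 3 sites")

    rows = []
    reports: dict[tuple[str, str, bool], EvaluationReport] = {}
    for selector in selectors:
        for gated in (True, False):
            # one selection per fold, reused by every classifier
            fold_selections = {}
            for held_out in sites:
                train_sites = [s for s in sites if s != held_out]
                result, _ = _fold_selection(
                    table, train_sites, task_classes, selector, gated, k,
                    pi_threshold, alpha, "noncancer", seed,
                    cfg.sfs_cv_iterations, cfg.sfs_cv_folds,
                )
                fold_selections[held_out] = result
            for classifier in classifiers:
                folds = []
                for held_out in sites:
                    result = fold_selections[held_out]
                    train = table[
                        table["site"].isin([s for s in sites if s != held_out])
                        & table["class"].isin(task_classes)
                    ]
                    test = table[(table["site"] == held_out)
                                 & table["class"].isin(task_classes)]
                    y_train = (train["class"] == task_classes[1]).to_numpy()
                    y_test = (test["class"] == task_classes[1]).to_numpy()
                    scores = fit_predict_scores(
                        train[result.features].to_numpy(), y_train,
                        test[result.features].to_numpy(), classifier,
                        seed=seed,
                    )
                    folds.append(
                        FoldRecord(
                            held_out_site=held_out, selector=selector,
                            classifier=classifier, gated=gated,
                            auc=empirical_auc_scores(scores, y_test),
                            selected_features=list(result.features),
                        )
                    )
                aucs = np.array([f.auc for f in folds])
                reports[(selector, classifier, gated)] = EvaluationReport(
                    task=task, selector=selector, classifier=classifier,
                    gated=gated, folds=folds, mean_auc=float(aucs.mean()),
                    std_auc=float(aucs.std()),
                    config_snapshot=cfg.snapshot(), seed=seed,
                )
    for selector in selectors:
        for classifier in classifiers:
            sd = reports[(selector, classifier, True)]
            d = reports[(selector, classifier, False)]
            rows.append(
                {
                    "selector": selector,
                    "classifier": classifier,
                    "auc_sd_mean": sd.mean_auc,
                    "auc_sd_std": sd.std_auc,
                    "auc_d_mean": d.mean_auc,
                    "auc_d_std": d.std_auc,
                    "pct_improvement": percent_improvement(
                        sd.mean_auc, d.mean_auc
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class NormalizationEffect:
    per_feature_delta: pd.Series       # PI(post) - PI(pre)
    pi_pre: pd.Series
    pi_post: pd.Series
    family_summary: pd.DataFrame | None = None


def normalization_effect(
    table_pre: pd.DataFrame,
    table_post: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "exact",
    repetitions: int = 100,
    subsample_size: int | None = None,
    seed: int = 0,
    family_map: dict[str, str] | None = None,
) -> NormalizationEffect:
    """Per-feature PI change under color normalization, with optional
    per-family means (the before/after family summary)."""
    feats = feature_columns_of(table_pre)
    if feats != feature_columns_of(table_post):
        raise ValueError("tables must share the same feature columns")
    pre_ids = set(table_pre["region_id"])
    if pre_ids != set(table_post["region_id"]):
        raise ValueError("tables must cover the same regions")
    kwargs = dict(alpha=alpha, mode=mode, repetitions=repetitions,
                  subsample_size=subsample_size, seed=seed)
    pi_pre = preparation_instability(table_pre, **kwargs).pi
    pi_post = preparation_instability(table_post, **kwargs).pi
    delta = pi_post - pi_pre
    family_summary = None
    if family_map is not None:
        rows = []
        for family in sorted(set(family_map.values())):
            members = [f for f in feats if family_map.get(f) == family]
            rows.append(
                {
                    "family": family,
                    "pi_pre_mean": float(pi_pre[members].mean()),
                    "pi_post_mean": float(pi_post[members].mean()),
                    "delta_mean": float(delta[members].mean()),
                }
            )
        family_summary = pd.DataFrame(rows)
    return NormalizationEffect(
        per_feature_delta=delta, pi_pre=pi_pre, pi_post=pi_post,
        family_summary=family_summary,
    )
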