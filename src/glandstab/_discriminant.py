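"""Closed-form Gaussian discriminants for inner cross-validation loops.

The per-feature AUC map and the sequential-forward-selection objective
both evaluate on the order of 10^5-10^6 tiny discriminant fits (d <= 5,
n < 200). These helpers implement plain LDA (shared covariance) / QDA
(per-class covariance) scoring directly in numpy with a small ridge on
the covariance for degenerate inputs. The evaluation module's final
classifiers are scikit-learn estimators; these are only the CV engines.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def _tie_ranks(scores: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with tie handling, via np.unique."""
    _, inv, cnt = np.unique(scores, return_inverse=True, return_counts=True)
    csum = np.cumsum(cnt)
    avg = csum - (cnt - 1) / 2.0
    return avg[inv]


def empirical_auc_scores(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC of continuous scores against binary labels via the rank
    (Mann-Whitney) formula; ties contribute one half."""
    y = np.asarray(y, dtype=bool)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = _tie_ranks(np.asarray(scores, dtype=float))
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


class GaussianDiscriminant:
    """LDA (``shared=True``) or QDA scoring with ridge regularization."""

    def __init__(self, shared: bool = False, reg: float = 1e-6) -> None:
        self.shared = shared
        self.reg = reg

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianDiscriminant":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1:
            x = x.T
        y = np.asarray(y, dtype=bool)
        d = x.shape[1]
        self.means_ = [x[~y].mean(axis=0), x[y].mean(axis=0)]
        self.priors_ = [float((~y).mean()), float(y.mean())]
        covs = []
        for cls in (~y, y):
            xc = x[cls] - x[cls].mean(axis=0)
            covs.append(xc.T @ xc / max(len(xc), 1))
        if self.shared:
            pooled = (
                covs[0] * (~y).sum() + covs[1] * y.sum()
            ) / len(y)
            covs = [pooled, pooled]
        self.covs_ = []
        for c in covs:
            ridge = self.reg * max(np.trace(c) / d, 1.0)
            self.covs_.append(c + ridge * np.eye(d))
        return self

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.means_[0]):
            x = x.T
        logps = []
        for mean, cov, prior in zip(self.means_, self.covs_, self.priors_):
            diff = x - mean
            sign, logdet = np.linalg.slogdet(cov)
            sol = np.linalg.solve(cov, diff.T).T
            maha = (diff * sol).sum(axis=1)
            logps.append(-0.5 * (maha + logdet) + np.log(max(prior, 1e-12)))
        return logps[1] - logps[0]


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Shuffled stratified fold assignment; yields (train, test) masks."""
    y = np.asarray(y, dtype=bool)
    assignment = np.empty(len(y), dtype=int)
    for cls in (True, False):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    for f in range(folds):
        test = assignment == f
        yield ~test, test


def cv_auc(
    x: np.ndarray,
    y: np.ndarray,
    iterations: int = 10,
    folds: int = 3,
    seed: int = 0,
    shared: bool = False,
) -> float:
    """Mean test AUC of a Gaussian discriminant over repeated stratified
    k-fold CV. Folds lacking a class are skipped."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(y, dtype=bool)
    d = x.shape[1]
    eye = np.eye(d)
    rng = np.random.default_rng(seed)
    total = 0.0
    count = 0
    for _ in range(iterations):
        for train, test in _stratified_folds(y, folds, rng):
            ytr, yte = y[train], y[test]
            if ytr.all() or not ytr.any() or yte.all() or not yte.any():
                continue
            xtr, xte = x[train], x[test]
            # inline Gaussian discriminant (hot path)
            logps = []
            if shared:
                means, pools = [], []
                for cls in (~ytr, ytr):
                    xc = xtr[cls]
                    mu = xc.mean(axis=0)
                    means.append(mu)
                    dev = xc - mu
                    pools.append(dev.T @ dev)
                cov = (pools[0] + pools[1]) / len(ytr)
                cov = cov + 1e-6 * max(np.trace(cov) / d, 1.0) * eye
                covs = [cov, cov]
            else:
                means, covs = [], []
                for cls in (~ytr, ytr):
                    xc = xtr[cls]
                    mu = xc.mean(axis=0)
                    dev = xc - mu
                    cov = dev.T @ dev / len(xc)
                    cov = cov + 1e-6 * max(np.trace(cov) / d, 1.0) * eye
                    means.append(mu)
                    covs.append(cov)
            priors = [1.0 - ytr.mean(), ytr.mean()]
            for mu, cov, prior in zip(means, covs, priors):
                diff = xte - mu
                _, logdet = np.linalg.slogdet(cov)
                sol = np.linalg.solve(cov, diff.T)
                maha = np.einsum("ij,ji->i", diff, sol)
                logps.append(-0.5 * (maha + logdet) + np.log(max(prior, 1e-12)))
            total += empirical_auc_scores(logps[1] - logps[0], yte)
            count += 1
    return float(total / count) if count else 0.5


def cv_auc_per_feature(
    x: np.ndarray,
    y: np.ndarray,
    iterations: int = 100,
    folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Vectorized per-feature 1-D LDA CV-AUC for an (n, F) matrix.

    For one feature, the LDA score is monotone in w * x with
    w = mean1 - mean0 (pooled variance only rescales), so the fold AUC
    reduces to a rank computation on the oriented test values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=bool)
    rng = np.random.default_rng(seed)
    n_feat = x.shape[1]
    total = np.zeros(n_feat)
    count = 0
    for _ in range(iterations):
        for train, test in _stratified_folds(y, folds, rng):
            ytr, yte = y[train], y[test]
            if ytr.all() or not ytr.any() or yte.all() or not yte.any():
                continue
            w = x[train][ytr].mean(axis=0) - x[train][~ytr].mean(axis=0)
            scores = x[test] * np.sign(w)[None, :]
            ranks = rankdata(scores, axis=0)
            n1 = int(yte.sum())
            n0 = len(yte) - n1
            u = ranks[yte].sum(axis=0) - n1 * (n1 + 1) / 2.0
            total += u / (n0 * n1)
            count += 1
    if count == 0:
        return np.full(n_feat, 0.5)
    return total / count
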