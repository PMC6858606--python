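"""Signature inference and evaluation: LASSO selection with upsampling,
stability selection, boosted-stump logistic classification and repeated
stratified-split ROC/AUC reporting.

The selection stage mirrors a two-cohort design: probes are selected on one
dataset (with minority-class upsampling against a 9-vs-135-style imbalance)
and the classifier is refit per training split — signature membership, never
fitted coefficients, is what transfers between cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_X_y, check_array

from ._boost import (
    lasso_logistic_path,
    logitboost_decision,
    logitboost_fit,
    loocv_iteration_accuracy,
)


def upsample_balance(
    X: np.ndarray, y: np.ndarray, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the minority class with replacement until classes balance.

    Majority rows are untouched; the output order is shuffled
    deterministically under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes to balance")
    if len(classes) > 2:
        raise ValueError("binary labels expected")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    idx_min = np.flatnonzero(y == minority)
    extra = rng.choice(idx_min, size=n_maj - n_min, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    rng.shuffle(idx)
    return X[idx], y[idx]


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _binomial_deviance(y: np.ndarray, eta: np.ndarray) -> float:
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-10, 1 - 1e-10)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, s in enumerate(idx):
            folds[i % n_folds].append(s)
    return [np.array(sorted(f)) for f in folds]


@dataclass
class LassoSelection:
    selected: list[int]
    coefficients: np.ndarray
    intercept: float
    chosen_lambda: float
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    cv_se: np.ndarray


def l1_logistic_select(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 100,
    cv_folds: int = 10,
    rule: str = "1se",
    seed: int = 0,
    lambda_min_ratio: float = 1e-3,
) -> LassoSelection:
    """L1-penalized logistic selection along a regularization path.

    X is standardized internally; the lambda path is log-spaced from
    lambda_max (the smallest penalty zeroing every coefficient) down to
    `lambda_min_ratio * lambda_max`; lambda is chosen by `cv_folds`-fold
    cross-validated binomial deviance under the 1-SE rule (or the minimum
    with rule="min"); selected features have nonzero coefficients there.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    Xs, mu, sd = _standardize(X)
    ybar = y.mean()
    lam_max = np.max(np.abs(Xs.T @ (y - ybar))) / n
    lam_max = max(lam_max, 1e-10)
    lambdas = np.exp(
        np.linspace(np.log(lam_max), np.log(lam_max * lambda_min_ratio), n_lambda)
    )
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, cv_folds, rng)
    dev = np.zeros((cv_folds, n_lambda))
    for fi, test_idx in enumerate(folds):
        train = np.setdiff1d(np.arange(n), test_idx)
        Xt, _, _ = _standardize(X[train])
        # re-standardize the held-out block with the training moments
        mu_t = X[train].mean(axis=0)
        sd_t = X[train].std(axis=0)
        sd_t = np.where(sd_t == 0, 1.0, sd_t)
        Xv = (X[test_idx] - mu_t) / sd_t
        b0s, betas = lasso_logistic_path(
            np.ascontiguousarray(Xt), y[train], lambdas
        )
        for li in range(n_lambda):
            eta = b0s[li] + Xv @ betas[li]
            dev[fi, li] = _binomial_deviance(y[test_idx], eta)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(cv_mean))
    if rule == "1se":
        bound = cv_mean[best] + cv_se[best]
        chosen = int(np.flatnonzero(cv_mean <= bound)[0])  # largest lambda within 1 SE
    elif rule == "min":
        chosen = best
    else:
        raise ValueError(f"unknown rule {rule!r}")
    b0s, betas = lasso_logistic_path(np.ascontiguousarray(Xs), y, lambdas)
    beta = betas[chosen]
    if not np.all(np.isfinite(beta)):
        raise RuntimeError("coordinate descent did not converge; inspect inputs")
    selected = [int(j) for j in np.flatnonzero(beta != 0)]
    return LassoSelection(
        selected=selected,
        coefficients=beta / sd,  # back on the original scale
        intercept=float(b0s[chosen] - np.sum(beta * mu / sd)),
        chosen_lambda=float(lambdas[chosen]),
        lambdas=lambdas,
        cv_deviance=cv_mean,
        cv_se=cv_se,
    )


@dataclass
class StabilityResult:
    probabilities: np.ndarray  # per candidate feature, in [0, 1]
    retained: list[int]
    B: int

    def as_series(self, names: Sequence[str] | None = None) -> pd.Series:
        idx = list(names) if names is not None else list(range(len(self.probabilities)))
        return pd.Series(self.probabilities, index=idx, name="selection_probability")


def stability_select(
    X: np.ndarray,
    y: np.ndarray,
    B: int = 2000,
    subsample: float = 0.5,
    threshold: float = 0.5,
    seed: int = 0,
    upsample: bool = True,
    **lasso_kwargs,
) -> StabilityResult:
    """Stability selection: selection probability of each feature over `B`
    subsampled L1-logistic fits; features with probability strictly above
    `threshold` are retained.

    Each replicate draws `subsample` of the rows without replacement (redrawn
    until both classes are present), balances classes by upsampling, and runs
    :func:`l1_logistic_select`.
    """
    if B < 50:
        import warnings

        warnings.warn("B < 50 gives unstable selection probabilities")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    m = max(2, int(round(n * subsample)))
    hits = np.zeros(p)
    for b in range(B):
        for _ in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if len(np.unique(y[idx])) == 2:
                break
        else:
            raise ValueError("could not draw a subsample containing both classes")
        Xb, yb = X[idx], y[idx]
        if upsample:
            Xb, yb = upsample_balance(Xb, yb, rng)
        sel = l1_logistic_select(
            Xb, yb, seed=int(rng.integers(0, 2**31 - 1)), **lasso_kwargs
        )
        hits[sel.selected] += 1
    prob = hits / B
    retained = [int(j) for j in np.flatnonzero(prob > threshold)]
    return StabilityResult(prob, retained, B)


class LogitBoostClassifier(BaseEstimator, ClassifierMixin):
    """Boosted logistic regression with decision stumps (LogitBoost).

    The number of boosting iterations is tuned on the training set by
    leave-one-out accuracy over `iteration_grid` (ties resolve to the fewest
    iterations); set tune="none" to always use `max_iters`.

    Attributes set by fit: classes_, n_iterations_, stumps_ (one row per
    iteration: feature index, threshold, left value, right value),
    loocv_accuracy_.
    """

    def __init__(
        self,
        max_iters: int = 100,
        tune: str = "loocv",
        iteration_grid: Sequence[int] | None = None,
    ):
        self.max_iters = max_iters
        self.tune = tune
        self.iteration_grid = iteration_grid

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("LogitBoostClassifier is binary; constant y invalid")
        Xc = np.ascontiguousarray(X, dtype=float)
        yf = y01.astype(float)
        grid = (
            np.array(sorted(self.iteration_grid), dtype=np.int64)
            if self.iteration_grid is not None
            else np.arange(5, self.max_iters + 1, 5, dtype=np.int64)
        )
        if self.tune == "loocv":
            acc = loocv_iteration_accuracy(Xc, yf, grid)
            best = int(grid[int(np.argmax(acc))])  # argmax takes first => fewest iters
            self.loocv_accuracy_ = dict(zip(grid.tolist(), acc.tolist()))
        elif self.tune == "none":
            best = self.max_iters
            self.loocv_accuracy_ = None
        else:
            raise ValueError(f"unknown tune mode {self.tune!r}")
        feats, thrs, lefts, rights = logitboost_fit(Xc, yf, best)
        self.n_iterations_ = best
        self.stumps_ = np.column_stack([feats.astype(float), thrs, lefts, rights])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_array(X)
        Xc = np.ascontiguousarray(X, dtype=float)
        feats = self.stumps_[:, 0].astype(np.int64)
        return logitboost_decision(
            Xc, feats, self.stumps_[:, 1], self.stumps_[:, 2], self.stumps_[:, 3],
            self.n_iterations_,
        )

    def predict_proba(self, X):
        F = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-2.0 * F))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes_.tolist(),
                "n_iterations": int(self.n_iterations_),
                "stumps": self.stumps_.tolist(),
            }
        )


def roc_auc(scores, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC (tie-aware Mann-Whitney U / (n1*n2)) and the ROC curve.

    Returns (auc, fpr, tpr)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need both classes present")
    pos = labels == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2
    auc = float(u / (n1 * n0))
    fpr, tpr, _ = _sk_roc_curve(pos.astype(int), scores)
    return auc, fpr, tpr


@dataclass
class EvalReport:
    aucs: list[float]
    mean_auc: float
    sd_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    n_splits: int

    def to_json(self) -> str:
        d = asdict(self)
        d["fpr_grid"] = self.fpr_grid.tolist()
        d["mean_tpr"] = self.mean_tpr.tolist()
        return json.dumps(d)


def evaluate_repeated(
    X: np.ndarray,
    y: np.ndarray,
    signature: Sequence[int],
    n_splits: int = 100,
    train_fraction: float = 0.7,
    seed: int = 0,
    max_iters: int = 100,
    tune: str = "loocv",
) -> EvalReport:
    """Repeated stratified 70/30 evaluation of a probe signature.

    Per split: stratified partition, minority upsampling on the training
    part only, LogitBoost on the signature columns, ROC/AUC on the held-out
    part.  Reports per-split AUCs, their mean and SD, and the vertically
    averaged ROC on a fixed 101-point FPR grid.
    """
    X = np.asarray(X, dtype=float)[:, list(signature)]
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 samples each for stratification")
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, random_state=seed
    )
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0, 1, 101)
    aucs = []
    tprs = []
    for tr, te in splitter.split(X, y):
        Xtr, ytr = upsample_balance(X[tr], y[tr], rng)
        clf = LogitBoostClassifier(max_iters=max_iters, tune=tune).fit(Xtr, ytr)
        scores = clf.decision_function(X[te])
        auc, fpr, tpr = roc_auc(scores, y[te])
        aucs.append(auc)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    sd = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
    return EvalReport(
        aucs=[float(a) for a in aucs],
        mean_auc=float(np.mean(aucs)),
        sd_auc=sd,
        fpr_grid=fpr_grid,
        mean_tpr=mean_tpr,
        n_splits=n_splits,
    )
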