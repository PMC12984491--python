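"""Missing-data handling, classifiers and stratified out-of-fold evaluation.

Two models are supported: L1-penalized logistic regression (liblinear,
C=0.1, features z-scored with training-fold statistics) and gradient-boosted
trees on raw values.  Evaluation is stratified 5-fold cross-validation with
out-of-fold probabilities; both the mean-across-folds and pooled-out-of-fold
AUC conventions are reported, labeled distinctly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold

DEFAULT_SEED = 20250719

TASKS: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    # positive classes first
    "HCM_vs_DCM-I": (("HCM", "HOCM", "HNCM", "HCM-unknown"), ("DCM-I",)),
    "HCM_vs_DCM-NI": (("HCM", "HOCM", "HNCM", "HCM-unknown"), ("DCM-NI",)),
    "HOCM_vs_HNCM": (("HOCM",), ("HNCM",)),
}

GBT_DEFAULTS = dict(n_estimators=200, max_depth=3, learning_rate=0.1, subsample=1.0)


class MlEvalError(Exception):
    pass


@dataclass
class AnalyticSubset:
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    dropped_features: list[str]
    excluded_records: list[str]
    record_ids: list[str]


@dataclass
class CvResult:
    task: str
    model: str
    fold_auc_roc: list[float]
    fold_auc_pr: list[float]
    oof_probabilities: list[float]
    fold_assignments: list[int]
    record_ids: list[str]
    labels: list[int]
    auc_roc_mean: float
    auc_pr_mean: float
    auc_roc_pooled: float
    auc_pr_pooled: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    seed: int
    n: int
    dropped_features: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "CvResult":
        return cls(**json.loads(text))


def missingness_prepare(
    features: pd.DataFrame, k_drop: int = 3
) -> AnalyticSubset:
    """Drop the k features with the most missing cells (ties alphabetical),
    then exclude rows with any remaining missing value."""
    if features.empty:
        raise MlEvalError("empty feature table")
    counts = features.isna().sum()
    order = sorted(features.columns, key=lambda c: (-counts[c], c))
    dropped = [c for c in order[:k_drop] if counts[c] > 0] if k_drop > 0 else []
    # features with zero missingness are never dropped
    kept = [c for c in features.columns if c not in dropped]
    sub = features[kept]
    complete = ~sub.isna().any(axis=1)
    if not complete.any():
        raise MlEvalError("complete-case filtering removed every record")
    excluded = list(sub.index[~complete])
    sub = sub[complete]
    return AnalyticSubset(
        X=sub.to_numpy(dtype=float),
        y=np.array([]),
        feature_names=kept,
        dropped_features=dropped,
        excluded_records=excluded,
        record_ids=list(sub.index),
    )


def fit_l1_logistic(X: np.ndarray, y: np.ndarray, inverse_reg: float = 0.1) -> LogisticRegression:
    """L1-penalized logistic regression (liblinear solver, unpenalized-style
    intercept).  X must already be standardized with training statistics."""
    if len(np.unique(y)) < 2:
        raise MlEvalError("single-class training labels")
    model = LogisticRegression(
        l1_ratio=1.0, C=inverse_reg, solver="liblinear", max_iter=2000, tol=1e-6,
        random_state=0,
    )
    model.fit(X, y)
    return model


def fit_gradient_boosting(
    X: np.ndarray, y: np.ndarray, params: Mapping | None = None, seed: int = DEFAULT_SEED
) -> GradientBoostingClassifier:
    """Additive trees on logistic-loss gradients with logged defaults."""
    if len(np.unique(y)) < 2:
        raise MlEvalError("single-class training labels")
    opts = dict(GBT_DEFAULTS)
    if params:
        opts.update(params)
    model = GradientBoostingClassifier(random_state=seed, **opts)
    model.fit(X, y)
    return model


class _FoldScaler:
    """Z-scoring with statistics from the training fold only."""

    def fit(self, X: np.ndarray) -> "_FoldScaler":
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.sd_


def stratified_oof_probabilities(
    model_name: str,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    gbt_params: Mapping | None = None,
    inverse_reg: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold probabilities and fold ids from stratified k-fold CV.

    All training-fold statistics (standardization for the linear model) are
    computed inside each training fold only.
    """
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise MlEvalError("labels must be binary")
    if counts.min() < k:
        raise MlEvalError(f"minority class has {counts.min()} members, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    proba = np.full(len(y), np.nan)
    folds = np.full(len(y), -1, dtype=int)
    for fold_id, (tr, te) in enumerate(skf.split(X, y)):
        Xtr, Xte = X[tr], X[te]
        if model_name == "l1_logistic":
            scaler = _FoldScaler().fit(Xtr)
            model = fit_l1_logistic(scaler.transform(Xtr), y[tr], inverse_reg)
            p = model.predict_proba(scaler.transform(Xte))[:, 1]
        elif model_name in ("gradient_boosting", "gbt"):
            model = fit_gradient_boosting(Xtr, y[tr], gbt_params, seed)
            p = model.predict_proba(Xte)[:, 1]
        else:
            raise MlEvalError(f"unknown model {model_name!r}")
        proba[te] = p
        folds[te] = fold_id
    assert not np.any(np.isnan(proba))
    return proba, folds


def auc_roc(y: Sequence[int], p: Sequence[float]) -> float | None:
    """Rank-statistic AUC with tie midranks (probability of superiority)."""
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        return None
    ranks = rankdata(p)
    u = float(np.sum(ranks[y == 1])) - n1 * (n1 + 1) / 2.0
    return u / (n1 * n0)


def auc_pr(y: Sequence[int], p: Sequence[float]) -> float | None:
    """Average precision (step-wise, no interpolation)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        return None
    return float(average_precision_score(y, np.asarray(p, dtype=float)))


def youden_threshold(y: Sequence[int], p: Sequence[float]) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidates are the unique probabilities; classification rule is
    p >= tau -> positive; ties resolved toward the lowest tau (favoring
    sensitivity).  Returns (tau, sensitivity, specificity).
    """
    y = np.asarray(y)
    p = np.asarray(p, dtype=float)
    pos = y == 1
    neg = y == 0
    if not pos.any() or not neg.any():
        raise MlEvalError("both classes required for Youden threshold")
    best: tuple[float, float, float] | None = None
    best_j = -np.inf
    for tau in np.unique(p):
        pred = p >= tau
        sens = float(np.sum(pred & pos)) / np.sum(pos)
        spec = float(np.sum(~pred & neg)) / np.sum(neg)
        j = sens + spec - 1.0
        if j > best_j or (j == best_j and best is not None and tau < best[0]):
            best_j = j
            best = (float(tau), sens, spec)
    assert best is not None
    return best


def evaluate_task(
    features: pd.DataFrame,
    labels: pd.Series,
    task: str,
    model: str,
    *,
    k: int = 5,
    seed: int = DEFAULT_SEED,
    top_k_features: int | None = None,
    k_drop: int = 3,
    gbt_params: Mapping | None = None,
) -> CvResult:
    """Run one binary task end to end.

    ``top_k_features`` restricts to the highest-|Cliff's delta| features
    (the convention used for the low-sample obstructive-vs-non-obstructive
    task); by default it is applied only for that task (15 features).
    """
    if task not in TASKS:
        raise MlEvalError(f"unknown task {task!r}; valid: {sorted(TASKS)}")
    pos_classes, neg_classes = TASKS[task]
    mask = labels.isin(pos_classes + neg_classes)
    sub_features = features[mask.to_numpy()]
    sub_labels = labels[mask.to_numpy()]
    y_full = sub_labels.isin(pos_classes).astype(int)
    if y_full.nunique() < 2:
        raise MlEvalError(f"task {task}: labels cover only one class")

    subset = missingness_prepare(sub_features, k_drop=k_drop)
    y = y_full.loc[subset.record_ids].to_numpy()
    X = subset.X
    names = subset.feature_names

    if top_k_features is None and task == "HOCM_vs_HNCM":
        top_k_features = 15
    if top_k_features:
        from .group_stats import compare_groups, rank_features

        df = pd.DataFrame(X, columns=names)
        lab = pd.Series(np.where(y == 1, "pos", "neg"))
        rows = compare_groups(df, lab, ("pos", "neg"))
        chosen = rank_features(rows, k=top_k_features)
        keep_idx = [names.index(c) for c in chosen]
        X = X[:, keep_idx]
        names = chosen

    proba, folds = stratified_oof_probabilities(
        model, X, y, k=k, seed=seed, gbt_params=gbt_params
    )
    fold_roc, fold_pr = [], []
    for f in range(k):
        m = folds == f
        r = auc_roc(y[m], proba[m])
        pr = auc_pr(y[m], proba[m])
        if r is not None:
            fold_roc.append(r)
        if pr is not None:
            fold_pr.append(pr)
    tau, sens, spec = youden_threshold(y, proba)
    return CvResult(
        task=task,
        model=model,
        fold_auc_roc=fold_roc,
        fold_auc_pr=fold_pr,
        oof_probabilities=[float(v) for v in proba],
        fold_assignments=[int(v) for v in folds],
        record_ids=[str(r) for r in subset.record_ids],
        labels=[int(v) for v in y],
        auc_roc_mean=float(np.mean(fold_roc)),
        auc_pr_mean=float(np.mean(fold_pr)),
        auc_roc_pooled=float(auc_roc(y, proba)),
        auc_pr_pooled=float(auc_pr(y, proba)),
        youden_threshold=tau,
        sensitivity=sens,
        specificity=spec,
        seed=seed,
        n=len(y),
        dropped_features=subset.dropped_features,
    )
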