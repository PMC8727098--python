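"""Model suite, stratified cross-validation, and evaluation metrics.

The suite mirrors the study's experimental set-up: bagging over near-full
decision trees (max 139 splits), AdaBoost over 20-split trees with learning
rate 0.1 (implemented in-repo, see :mod:`ovsurv.boosting`), a random forest
with pinned seed 0 and unlimited depth, a 100-tree gradient-boosted
ensemble, and logistic regression as the statistical baseline.  Each model
is evaluated under stratified 10-fold cross-validation; metrics are
computed on the pooled out-of-fold predictions with "survived" as the
positive class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .boosting import AdaBoostTreeClassifier

METHODS = ("bagging", "adaboost", "random_forest", "gradient_boosting", "logistic")


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier plus hyperparameter overrides."""

    method: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")


def default_model_specs() -> list[ModelSpec]:
    """The study's model suite with its published settings."""
    return [
        ModelSpec("bagging", {"max_splits": 139}),
        ModelSpec("adaboost", {"max_splits": 20, "learning_rate": 0.1}),
        ModelSpec("random_forest", {"seed": 0, "max_depth": None}),
        ModelSpec("gradient_boosting", {"n_estimators": 100}),
        ModelSpec("logistic", {}),
    ]


def make_classifier(spec: ModelSpec, seed: int | None = None) -> BaseEstimator:
    """Instantiate the estimator behind a ModelSpec.

    ``seed`` feeds any stochastic model unless the spec pins its own
    (the random forest pins seed 0, as in the study).
    """
    hp = dict(spec.hyperparameters)
    if spec.method == "bagging":
        # a "learning rate" is sometimes listed for bagging; it has no meaning
        # there and is ignored
        hp.pop("learning_rate", None)
        base = DecisionTreeClassifier(max_leaf_nodes=hp.pop("max_splits", 139) + 1)
        return BaggingClassifier(
            estimator=base,
            n_estimators=hp.pop("n_estimators", 30),
            random_state=hp.pop("seed", seed),
        )
    if spec.method == "adaboost":
        return AdaBoostTreeClassifier(
            n_estimators=hp.pop("n_estimators", 50),
            max_splits=hp.pop("max_splits", 20),
            learning_rate=hp.pop("learning_rate", 0.1),
            random_state=hp.pop("seed", seed),
        )
    if spec.method == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            max_depth=hp.pop("max_depth", None),
            random_state=hp.pop("seed", 0),
        )
    if spec.method == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 100),
            random_state=hp.pop("seed", seed),
        )
    return LogisticRegression(max_iter=hp.pop("max_iter", 1000))


class Metrics(NamedTuple):
    accuracy_pct: float
    sensitivity: float
    specificity: float
    auc: float


def metrics(predictions, scores, labels, positive: int = 1) -> Metrics:
    """Accuracy (%), sensitivity, specificity and rank-statistic AUC.

    "Survived" is the positive class: sensitivity = TP/(TP+FN) over true
    survivors, specificity = TN/(TN+FP) over true non-survivors.  The AUC is
    the Mann-Whitney rank statistic with half-credit for tied scores, which
    equals the trapezoidal ROC area.
    """
    pred = np.asarray(predictions)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if not (len(pred) == len(s) == len(y)):
        raise ValueError("predictions, scores and labels differ in length")
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes among the labels")
    tp = int(((pred == positive) & pos).sum())
    tn = int(((pred != positive) & ~pos).sum())
    ranks = rankdata(s)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return Metrics(
        accuracy_pct=100.0 * (tp + tn) / len(y),
        sensitivity=tp / n_pos,
        specificity=tn / n_neg,
        auc=float(auc),
    )


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and metrics for one model."""

    fold_assignments: np.ndarray
    fold_accuracies: list[float]
    predictions: np.ndarray
    scores: np.ndarray
    labels: np.ndarray
    accuracy_pct: float
    sensitivity: float
    specificity: float
    auc: float

    @property
    def fold_signature(self) -> tuple:
        """Hashable identity of the fold partition (for shared-fold checks)."""
        return tuple(self.fold_assignments.tolist())


def _scores_of(est: BaseEstimator, X: np.ndarray) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return expit(est.decision_function(X))


def fit_predict(model, X_train, y_train, X_test, seed: int | None = None):
    """Fit one model and score a test set; returns (predictions, scores)."""
    est = make_classifier(model, seed) if isinstance(model, ModelSpec) else clone(model)
    Xtr = np.asarray(X_train, dtype=float)
    Xte = np.asarray(X_test, dtype=float)
    est.fit(Xtr, np.asarray(y_train))
    return est.predict(Xte), _scores_of(est, Xte)


def cross_validate(
    X,
    y,
    model,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """k-fold CV; metrics from pooled out-of-fold predictions.

    Folds are stratified by default so every training split contains both
    classes even in small cohorts; per-fold accuracies are retained for
    paired significance testing.
    """
    X = np.asarray(X.to_numpy() if isinstance(X, pd.DataFrame) else X, dtype=float)
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if stratified and counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} patients < k={k}; use a smaller k"
        )
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)

    n = len(y)
    assignments = np.empty(n, dtype=int)
    oof_pred = np.empty(n, dtype=y.dtype)
    oof_score = np.empty(n, dtype=float)
    fold_accuracies = []
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        pred, score = fit_predict(model, X[train], y[train], X[test], seed=seed + fold)
        assignments[test] = fold
        oof_pred[test] = pred
        oof_score[test] = score
        fold_accuracies.append(float((pred == y[test]).mean()))
    m = metrics(oof_pred, oof_score, y)
    return CVResult(
        fold_assignments=assignments,
        fold_accuracies=fold_accuracies,
        predictions=oof_pred,
        scores=oof_score,
        labels=y,
        accuracy_pct=m.accuracy_pct,
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        auc=m.auc,
    )
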