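"""Discrete two-class AdaBoost over depth-limited decision trees.

One boosting round fits a weak tree under the current instance weights,
takes its weighted training error e = sum of weights over misclassified
instances, gives the tree a vote of log((1-e)/e), multiplies the weights of
*correctly* classified instances by e/(1-e), and renormalises the weights
to sum to one — so hard instances gain relative weight.  A zero error is
clamped to 1e-10 so the vote stays finite; a round with e >= 0.5 (vote
would be non-positive) is discarded, the instance weights are re-drawn once
at random, and boosting stops if the retry also fails.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

_EPS = 1e-10


def adaboost_round(instance_weights, misclassified_mask):
    """One weight update: returns (error_rate, vote_weight, updated_weights).

    ``instance_weights`` must be positive and sum to 1.  The error is the
    weight mass on misclassified instances; the vote is log((1-e)/e) with e
    clamped to [1e-10, 1-1e-10]; correctly classified instances have their
    weight multiplied by e/(1-e) before renormalisation.
    """
    w = np.asarray(instance_weights, dtype=float)
    mis = np.asarray(misclassified_mask, dtype=bool)
    if w.shape != mis.shape:
        raise ValueError("weights and mask differ in length")
    if (w <= 0).any():
        raise ValueError("instance weights must be positive")
    if not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("instance weights must sum to 1")
    error = float(w[mis].sum())
    e = min(max(error, _EPS), 1.0 - _EPS)
    vote = float(np.log((1.0 - e) / e))
    updated = w.copy()
    updated[~mis] *= e / (1.0 - e)
    updated /= updated.sum()
    return error, vote, updated


class AdaBoostTreeClassifier(BaseEstimator, ClassifierMixin):
    """AdaBoost ensemble of weight-fitted decision trees (binary labels).

    Parameters
    ----------
    n_estimators : int
        Maximum number of boosting rounds.
    max_splits : int
        Maximum internal splits per weak tree (a tree with L leaves has
        L-1 splits, so this maps to ``max_leaf_nodes = max_splits + 1``).
    learning_rate : float
        Multiplier on each tree's vote weight.
    random_state : int or None
        Seeds tree tie-breaking and the one weight re-draw.

    Attributes
    ----------
    classes_ : ndarray of the two class labels
    estimators_ : list of fitted trees
    votes_ : ndarray of (learning-rate-scaled) vote weights
    errors_ : ndarray of weighted training errors per kept round
    """

    def __init__(
        self,
        n_estimators: int = 50,
        max_splits: int = 20,
        learning_rate: float = 0.1,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_splits = max_splits
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly two classes in the training data, got "
                f"{list(self.classes_)}; stratify the folds"
            )
        sign = np.where(y == self.classes_[1], 1, -1)
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_, votes, errors = [], [], []
        redraw_used = False
        for _ in range(self.n_estimators):
            tree = DecisionTreeClassifier(
                max_leaf_nodes=max(2, self.max_splits + 1),
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X, sign, sample_weight=w * n)
            mis = tree.predict(X) != sign
            error = float(w[mis].sum())
            if error >= 0.5:
                if redraw_used:
                    break
                redraw_used = True  # discard round, re-draw weights once
                w = rng.dirichlet(np.ones(n))
                continue
            error, vote, w = adaboost_round(w, mis)
            self.estimators_.append(tree)
            votes.append(self.learning_rate * vote)
            errors.append(error)
            if error <= _EPS:  # perfect weak learner: nothing left to reweight
                break
        if not self.estimators_:
            raise ValueError("no boosting round achieved error < 0.5")
        self.votes_ = np.asarray(votes)
        self.errors_ = np.asarray(errors)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "estimators_")
        X = check_array(X)
        margin = np.zeros(X.shape[0])
        for tree, vote in zip(self.estimators_, self.votes_):
            margin += vote * tree.predict(X)
        return margin

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, self.classes_[1], self.classes_[0])

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])
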