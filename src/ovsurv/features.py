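"""Time-binned treatment-transition features and information-gain selection.

The follow-up horizon (36 months) is divided into equal bins of 1–6 months;
a binary column ``X_Tk_Y`` marks that treatment Y immediately followed
treatment X with the inter-event gap falling in bin k.  Bins are half-open
on the left, ``((k-1)*w, k*w]``, so "within one month" is T1 (a gap of
exactly zero also counts as T1).  The untimed baseline matrix records only
which treatments a patient ever received, irrespective of order.

Feature selection uses information gain,
``Gain(A) = H(D) - sum_v |D_v|/|D| * H(D_v)``,
with entropies in bits; columns with gain strictly above zero are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .mining import Pattern, TreatmentSequenceDB

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class BinScheme:
    """Equal-width month bins over the follow-up horizon.

    When the width does not divide the horizon (e.g. 5-month bins over 36
    months) the final bin is truncated at the horizon, so ``n_bins`` is the
    ceiling of horizon / width.
    """

    width_months: int
    horizon_months: int = 36

    def __post_init__(self) -> None:
        if self.width_months < 1 or self.horizon_months < 1:
            raise ValueError("width_months and horizon_months must be positive")
        if self.width_months > self.horizon_months:
            raise ValueError("width_months cannot exceed horizon_months")

    @property
    def n_bins(self) -> int:
        return -(-self.horizon_months // self.width_months)


def bin_index(gap_months: float, scheme: BinScheme) -> int | None:
    """1-based bin for an inter-treatment gap; None when past the horizon."""
    if gap_months < 0:
        raise ValueError(f"gap must be non-negative, got {gap_months}")
    if gap_months > scheme.horizon_months:
        return None
    if gap_months == 0:
        return 1
    return int(np.ceil(gap_months / scheme.width_months - _TIE_EPS))


@dataclass
class FeatureMatrix:
    """Binary patient x feature table with an aligned binary label vector."""

    X: pd.DataFrame
    y: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        values = self.X.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("feature values must be binary")
        if self.y is not None:
            if len(self.y) != len(self.X):
                raise ValueError("labels and rows differ in length")
            self.y = pd.Series(np.asarray(self.y), index=self.X.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.X.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


class TimedTransitionFeaturizer(BaseEstimator, TransformerMixin):
    """Encode adjacent treatment pairs into time-binned binary columns.

    Only length-2 frequent patterns (X, Y) generate columns; one column per
    bin, named ``X_Tk_Y``.  A column fires when Y immediately follows X (no
    intervening treatment) with the gap in bin k; a pair recurring with
    different gaps sets every matching bin column.  All-zero columns are
    dropped; order is pattern order then k ascending.
    """

    def __init__(self, patterns: list[Pattern], scheme: BinScheme):
        self.patterns = patterns
        self.scheme = scheme

    def fit(self, db: TreatmentSequenceDB, y=None) -> "TimedTransitionFeaturizer":
        pairs = []
        for p in self.patterns:
            symbols = tuple(p.symbols) if isinstance(p, Pattern) else tuple(p)
            for s in symbols:
                if s not in db.alphabet:
                    raise ValueError(f"pattern symbol {s!r} not in database alphabet")
            if len(symbols) == 2:
                pairs.append(symbols)
        self.pairs_ = pairs
        return self

    def transform(self, db: TreatmentSequenceDB) -> pd.DataFrame:
        columns = {
            f"{x}_T{k}_{y}": np.zeros(len(db), dtype=np.int8)
            for x, y in self.pairs_
            for k in range(1, self.scheme.n_bins + 1)
        }
        pids = list(db.sequences)
        for row, pid in enumerate(pids):
            seq = db.sequences[pid]
            for (sa, ta), (sb, tb) in zip(seq, seq[1:]):
                if (sa, sb) in self.pairs_:
                    k = bin_index(tb - ta, self.scheme)
                    if k is not None:
                        columns[f"{sa}_T{k}_{sb}"][row] = 1
        frame = pd.DataFrame(columns, index=pd.Index(pids, name="patient_id"))
        return frame.loc[:, frame.any(axis=0)]


def build_timed_matrix(
    db: TreatmentSequenceDB,
    patterns: list[Pattern],
    scheme: BinScheme,
    labels: pd.Series | None = None,
) -> FeatureMatrix:
    X = TimedTransitionFeaturizer(patterns, scheme).fit(db).transform(db)
    y = None if labels is None else pd.Series(labels).reindex(X.index)
    return FeatureMatrix(X=X, y=y)


def build_untimed_matrix(
    db: TreatmentSequenceDB, labels: pd.Series | None = None
) -> FeatureMatrix:
    """One column per treatment: 1 iff the patient ever received it."""
    if len(db) == 0:
        raise ValueError("sequence database is empty")
    pids = list(db.sequences)
    data = {
        sym: np.array(
            [int(any(s == sym for s, _ in db.sequences[pid])) for pid in pids],
            dtype=np.int8,
        )
        for sym in db.alphabet
    }
    X = pd.DataFrame(data, index=pd.Index(pids, name="patient_id"))
    y = None if labels is None else pd.Series(labels).reindex(X.index)
    return FeatureMatrix(X=X, y=y)


def entropy(labels) -> float:
    """Shannon entropy of the label distribution, in bits (0*log0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def info_gain(feature_column, labels) -> float:
    """Reduction in label entropy from conditioning on the feature."""
    col = np.asarray(feature_column)
    y = np.asarray(labels)
    if col.shape != y.shape:
        raise ValueError(f"length mismatch: {col.shape} vs {y.shape}")
    h = entropy(y)
    cond = 0.0
    for v in np.unique(col):
        mask = col == v
        cond += mask.mean() * entropy(y[mask])
    return h - cond


class InfoGainSelector(BaseEstimator, TransformerMixin):
    """Keep columns whose information gain exceeds a threshold (default 0).

    Attributes
    ----------
    gains_ : pd.Series, gain per input column
    support_ : boolean mask over input columns
    report_ : DataFrame (feature, information_gain) sorted descending
    """

    def __init__(self, threshold: float = 0.0):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y) -> "InfoGainSelector":
        y = np.asarray(y)
        self.gains_ = pd.Series(
            {c: info_gain(X[c].to_numpy(), y) for c in X.columns}, dtype=float
        )
        self.support_ = (self.gains_ > self.threshold + _TIE_EPS).to_numpy()
        report = self.gains_.sort_values(ascending=False, kind="stable")
        self.report_ = pd.DataFrame(
            {"feature": report.index, "information_gain": report.to_numpy()}
        )
        if not self.support_.any():
            warnings.warn("information-gain selection kept no features", stacklevel=2)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X.loc[:, self.support_]


class FoldwiseIGSelector(BaseEstimator, TransformerMixin):
    """Information-gain selection refitted inside each CV fold.

    Full-dataset selection before cross-validation (the in-study protocol)
    leaks label information into the folds; placing this transformer in a
    pipeline ahead of the classifier restricts the gain computation to each
    training split.  Only the columns flagged in ``candidate_mask`` (the
    binary treatment columns) compete; the rest pass through untouched.

    Attributes
    ----------
    keep_idx_ : ndarray of retained column indices (passthrough + selected)
    """

    def __init__(self, candidate_mask, threshold: float = 0.0):
        self.candidate_mask = candidate_mask
        self.threshold = threshold

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        mask = np.asarray(self.candidate_mask, dtype=bool)
        if mask.shape != (X.shape[1],):
            raise ValueError("candidate_mask length must equal the number of columns")
        keep = ~mask
        for j in np.where(mask)[0]:
            if info_gain(X[:, j], y) > self.threshold + _TIE_EPS:
                keep[j] = True
        self.keep_idx_ = np.where(keep)[0]
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.keep_idx_]


def select_by_ig(
    matrix: FeatureMatrix, threshold: float = 0.0
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """IG-select columns of a labelled FeatureMatrix; returns (matrix, report)."""
    if matrix.y is None:
        raise ValueError("FeatureMatrix needs labels for information-gain selection")
    selector = InfoGainSelector(threshold=threshold).fit(matrix.X, matrix.y)
    return FeatureMatrix(X=selector.transform(matrix.X), y=matrix.y), selector.report_
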