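"""Clinical-profile cleaning, class-conditional imputation, and summaries.

Cleaning follows the study protocol: patients with an unknown 3-year
survival label are removed, as are patients missing strictly more than half
of the six clinical attributes (age, CA-125, ascites, grade, stage,
histology).  Remaining gaps are filled class-conditionally — numeric
attributes with the mean of same-label patients, nominal attributes with
the mode of same-label patients — falling back to overall statistics when a
whole class lacks observations.  Mode ties break to the lexicographically
smallest category so the pipeline is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .comorbidity import CCIWeights, DEFAULT_CCI, compute_cci
from .cohort import CLINICAL_FIELDS, PatientRecord

NUMERIC_FIELDS: tuple[str, ...] = ("age", "ca125")
NOMINAL_FIELDS: tuple[str, ...] = ("ascites", "grade", "stage", "histology")


class EmptyCohortError(ValueError):
    """Cleaning removed every patient."""


@dataclass
class CleaningReport:
    n_input: int = 0
    n_dropped_missing_label: int = 0
    n_dropped_high_missing: int = 0
    n_imputed_cells: int = 0
    #: (field, class label) -> value used to fill
    imputation_values: dict = field(default_factory=dict)
    #: (field, class label) pairs where the mode was tied
    ties: list = field(default_factory=list)
    #: fields whose class statistic fell back to the overall statistic
    fallbacks: list = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_dropped_missing_label - self.n_dropped_high_missing


def cohort_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Clinical fields + ecog + label as a DataFrame indexed by patient_id."""
    rows = []
    for rec in cohort:
        row = {"patient_id": rec.patient_id}
        for f in CLINICAL_FIELDS:
            row[f] = getattr(rec, f)
        row["ecog"] = rec.ecog
        row["survived_3yr"] = rec.survived_3yr
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def drop_unusable(cohort: list[PatientRecord]) -> tuple[list[PatientRecord], CleaningReport]:
    """Remove patients with a missing label or > 50% missing clinical fields."""
    if not cohort:
        raise ValueError("cohort is empty")
    report = CleaningReport(n_input=len(cohort))
    kept: list[PatientRecord] = []
    for rec in cohort:
        if rec.survived_3yr is None:
            report.n_dropped_missing_label += 1
        elif rec.clinical_missing_fraction() > 0.5:  # strictly greater
            report.n_dropped_high_missing += 1
        else:
            kept.append(rec)
    if not kept:
        raise EmptyCohortError("cleaning removed every patient")
    return kept, report


class ClassConditionalImputer(BaseEstimator, TransformerMixin):
    """Fill missing cells with the per-class mean (numeric) or mode (nominal).

    Fit statistics are computed from observed cells of patients sharing the
    survival label; ``transform`` needs that label, so it accepts ``y``.
    Mode ties resolve to the lexicographically smallest category (by string
    form) and are recorded in ``ties_``.

    Attributes
    ----------
    fill_values_ : dict
        (column, class) -> fill value; class ``None`` holds the overall
        fallback used when a class has no observed values.
    ties_ : list of (column, class)
    """

    def __init__(
        self,
        numeric_fields: tuple[str, ...] = NUMERIC_FIELDS,
        nominal_fields: tuple[str, ...] = NOMINAL_FIELDS,
    ):
        self.numeric_fields = numeric_fields
        self.nominal_fields = nominal_fields

    @staticmethod
    def _mode(values: pd.Series) -> tuple[object, bool]:
        counts = values.value_counts()
        top = counts[counts == counts.iloc[0]].index.tolist()
        winner = sorted(top, key=str)[0]
        return winner, len(top) > 1

    def fit(self, X: pd.DataFrame, y) -> "ClassConditionalImputer":
        y = pd.Series(np.asarray(y), index=X.index)
        if y.isna().any():
            raise ValueError("every patient needs a survival label before imputation")
        self.classes_ = sorted(y.unique())
        self.fill_values_ = {}
        self.ties_ = []
        for col in self.numeric_fields:
            obs = X[col].dropna()
            if len(obs):
                self.fill_values_[(col, None)] = float(obs.mean())
            for cls in self.classes_:
                obs_c = X.loc[y == cls, col].dropna()
                if len(obs_c):
                    self.fill_values_[(col, cls)] = float(obs_c.mean())
        for col in self.nominal_fields:
            obs = X[col].dropna()
            if len(obs):
                self.fill_values_[(col, None)] = self._mode(obs)[0]
            for cls in self.classes_:
                obs_c = X.loc[y == cls, col].dropna()
                if len(obs_c):
                    value, tied = self._mode(obs_c)
                    self.fill_values_[(col, cls)] = value
                    if tied:
                        self.ties_.append((col, cls))
        return self

    def transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        if y is None:
            cls_of = pd.Series([None] * len(X), index=X.index, dtype=object)
        else:
            cls_of = pd.Series(np.asarray(y), index=X.index)
        out = X.copy()
        self.n_imputed_ = 0
        self.fallbacks_ = []
        for col in (*self.numeric_fields, *self.nominal_fields):
            for idx in out.index[out[col].isna()]:
                key = (col, cls_of[idx])
                if key not in self.fill_values_:
                    key = (col, None)
                    self.fallbacks_.append((col, cls_of[idx]))
                if key not in self.fill_values_:
                    raise ValueError(f"no observed values anywhere for field {col!r}")
                out.loc[idx, col] = self.fill_values_[key]
                self.n_imputed_ += 1
        return out


def impute_class_conditional(
    cohort: list[PatientRecord],
) -> tuple[list[PatientRecord], CleaningReport]:
    """Class-conditional mean/mode imputation over the clinical fields."""
    if any(rec.survived_3yr is None for rec in cohort):
        raise ValueError("every patient needs a survival label before imputation")
    frame = cohort_frame(cohort)
    y = frame["survived_3yr"]
    imputer = ClassConditionalImputer()
    filled = imputer.fit(frame, y).transform(frame, y)

    report = CleaningReport(
        n_input=len(cohort),
        n_imputed_cells=imputer.n_imputed_,
        imputation_values=dict(imputer.fill_values_),
        ties=list(imputer.ties_),
        fallbacks=list(imputer.fallbacks_),
    )
    out = []
    for rec in cohort:
        row = filled.loc[rec.patient_id]
        out.append(
            replace(
                rec,
                age=float(row["age"]),
                ca125=float(row["ca125"]),
                ascites=str(row["ascites"]),
                grade=int(row["grade"]),
                stage=str(row["stage"]),
                histology=str(row["histology"]),
            )
        )
    return out, report


def clean(cohort: list[PatientRecord]) -> tuple[list[PatientRecord], CleaningReport]:
    """drop_unusable followed by impute_class_conditional, reports merged."""
    kept, drop_report = drop_unusable(cohort)
    imputed, imp_report = impute_class_conditional(kept)
    drop_report.n_imputed_cells = imp_report.n_imputed_cells
    drop_report.imputation_values = imp_report.imputation_values
    drop_report.ties = imp_report.ties
    drop_report.fallbacks = imp_report.fallbacks
    return imputed, drop_report


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

_AGE_EDGES = [17, 40, 50, 60, 70, 80]


@dataclass
class CohortSummary:
    n_patients: int
    n_survivors: int
    overall_survival_rate_pct: float
    attributes: pd.DataFrame
    survival_by_group: pd.DataFrame


def _rate_pct(survived: pd.Series) -> float:
    return round(100.0 * survived.mean(), 2)


def summarize(cohort: list[PatientRecord], cci_weights: CCIWeights = DEFAULT_CCI) -> CohortSummary:
    """Attribute ranges/counts and survival rate per attribute group.

    Survival rate of a group is survivors / patients, in percent.
    """
    frame = cohort_frame(cohort)
    if frame["survived_3yr"].isna().any():
        raise ValueError("summarize expects a cleaned cohort (labels present)")
    frame["cci"] = [compute_cci(rec.comorbidity_flags, cci_weights) for rec in cohort]
    y = frame["survived_3yr"].astype(int)

    attr_rows = []
    for col in ("age", "ca125", "cci", "ecog"):
        attr_rows.append(
            {
                "attribute": col,
                "kind": "numeric",
                "summary": f"{frame[col].min():g}-{frame[col].max():g} "
                f"(median: {frame[col].median():g})",
            }
        )
    for col in ("ascites", "grade", "stage", "histology"):
        counts = frame[col].value_counts().sort_index()
        attr_rows.append(
            {
                "attribute": col,
                "kind": "nominal",
                "summary": "; ".join(f"{k}: {v}" for k, v in counts.items()),
            }
        )
    attributes = pd.DataFrame(attr_rows)

    group_rows = []
    age_group = pd.cut(
        frame["age"], bins=_AGE_EDGES, include_lowest=True,
        labels=[f"{lo}-{hi}" for lo, hi in zip(_AGE_EDGES, _AGE_EDGES[1:])],
    ).astype(object)
    groupers = {
        "age_group": age_group,
        "ascites": frame["ascites"],
        "grade": frame["grade"],
        "stage": frame["stage"],
        "ecog": frame["ecog"],
        "cci": frame["cci"],
    }
    for attr, series in groupers.items():
        for value, idx in series.groupby(series).groups.items():
            sub = y.loc[idx]
            group_rows.append(
                {
                    "attribute": attr,
                    "group": value,
                    "n": len(sub),
                    "survivors": int(sub.sum()),
                    "survival_rate_pct": _rate_pct(sub),
                }
            )
    return CohortSummary(
        n_patients=len(frame),
        n_survivors=int(y.sum()),
        overall_survival_rate_pct=_rate_pct(y),
        attributes=attributes,
        survival_by_group=pd.DataFrame(group_rows),
    )
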