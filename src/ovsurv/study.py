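"""Experiment orchestration: interval sweep, profile ablation, timed-vs-untimed.

Reproduces the structure of the study's experiments on any cohort:

* interval sweep — for each bin width (1..6 months): mine frequent
  substrings, build the timed matrix, select by information gain, join with
  the clinical and life-quality profiles, cross-validate every model;
* profile ablation — cross-validate each profile (clinical, treatment,
  life quality) separately at one bin width and report the best model;
* sequence ablation — timed pipeline versus the untimed
  treatments-ever-received baseline on identical folds;
* paired one-sided t-test over the shared per-fold accuracies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CVResult, ModelSpec, cross_validate, default_model_specs
from .cohort import PatientRecord
from .comorbidity import CCIWeights, DEFAULT_CCI, attach_life_quality
from .features import BinScheme, build_timed_matrix, build_untimed_matrix, select_by_ig
from .mining import build_sequence_db, mine_frequent_substrings
from .prep import cohort_frame

PROFILES = ("clinical", "treatment", "life_quality")

_STAGE_ORD = {"3a": 0, "3b": 1, "3c": 2, "4": 3}


@dataclass(frozen=True)
class ExperimentConfig:
    widths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    minsup: float = 0.05
    horizon_months: int = 36
    models: tuple[ModelSpec, ...] = field(default_factory=lambda: tuple(default_model_specs()))
    folds: int = 10
    seed: int = 0
    profiles: tuple[str, ...] = PROFILES
    cci_weights: CCIWeights = DEFAULT_CCI

    def __post_init__(self) -> None:
        for w in self.widths:
            if not 1 <= w <= self.horizon_months:
                raise ValueError(f"width {w} outside 1..{self.horizon_months}")
        if not self.profiles:
            raise ValueError("profiles must be non-empty")


def labels_of(cohort: list[PatientRecord]) -> pd.Series:
    y = cohort_frame(cohort)["survived_3yr"]
    if y.isna().any():
        raise ValueError("cohort has unlabelled patients; clean it first")
    return y.astype(int)


def clinical_design(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Numeric design matrix of the clinical profile (imputed cohort).

    CA-125 spans four orders of magnitude, so it enters on a log10 scale;
    FIGO substage is ordinal-coded and histology one-hot encoded.
    """
    frame = cohort_frame(cohort)
    clin = frame[["age", "ca125", "ascites", "grade", "stage", "histology"]]
    if clin.isna().any().any():
        raise ValueError("clinical design needs an imputed cohort")
    X = pd.DataFrame(index=frame.index)
    X["age"] = frame["age"].astype(float)
    X["log_ca125"] = np.log10(frame["ca125"].astype(float))
    X["ascites"] = (frame["ascites"] == "yes").astype(int)
    X["grade"] = frame["grade"].astype(int)
    X["stage_ord"] = frame["stage"].map(_STAGE_ORD).astype(int)
    for h in sorted(frame["histology"].unique()):
        X[f"hist_{h}"] = (frame["histology"] == h).astype(int)
    return X


def life_quality_design(
    cohort: list[PatientRecord], weights: CCIWeights = DEFAULT_CCI
) -> pd.DataFrame:
    return attach_life_quality(cohort, weights).astype(float)


def treatment_design(
    cohort: list[PatientRecord],
    width: int,
    minsup: float = 0.05,
    horizon: int = 36,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Timed, IG-selected treatment matrix; returns (X, information-gain report)."""
    y = labels_of(cohort)
    db = build_sequence_db(cohort)
    patterns = mine_frequent_substrings(db, minsup)
    matrix = build_timed_matrix(db, patterns, BinScheme(width, horizon), labels=y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty selection handled by callers
        selected, report = select_by_ig(matrix)
    return selected.X.astype(float), report


def untimed_design(cohort: list[PatientRecord]) -> pd.DataFrame:
    db = build_sequence_db(cohort)
    return build_untimed_matrix(db).X.astype(float)


def _join(parts: list[pd.DataFrame]) -> pd.DataFrame:
    out = pd.concat(parts, axis=1)
    if out.isna().any().any():
        raise ValueError("design matrices do not share a patient index")
    return out


def _row(width, model: ModelSpec, res: CVResult, n_features: int) -> dict:
    return {
        "width_months": width,
        "model": model.method,
        "accuracy_pct": res.accuracy_pct,
        "sensitivity": res.sensitivity,
        "specificity": res.specificity,
        "auc": res.auc,
        "n_features": n_features,
    }


def run_interval_sweep(cohort: list[PatientRecord], config: ExperimentConfig) -> pd.DataFrame:
    """Integrated (clinical + life-quality + timed treatment) CV per width and model."""
    y = labels_of(cohort)
    clin = clinical_design(cohort)
    lq = life_quality_design(cohort, config.cci_weights)
    rows = []
    for width in config.widths:
        Xt, _ = treatment_design(cohort, width, config.minsup, config.horizon_months)
        parts = [clin, lq]
        if Xt.shape[1]:
            parts.append(Xt)
        else:
            warnings.warn(f"width {width}: no treatment feature survived selection")
        X = _join(parts)
        for model in config.models:
            res = cross_validate(X, y, model, k=config.folds, seed=config.seed)
            rows.append(_row(width, model, res, X.shape[1]))
    return pd.DataFrame(rows)


def run_profile_ablation(
    cohort: list[PatientRecord], config: ExperimentConfig, width: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-profile CV at one bin width; returns (all rows, best model per profile)."""
    y = labels_of(cohort)
    designs: dict[str, pd.DataFrame] = {}
    if "clinical" in config.profiles:
        designs["clinical"] = clinical_design(cohort)
    if "treatment" in config.profiles:
        Xt, _ = treatment_design(cohort, width, config.minsup, config.horizon_months)
        if Xt.shape[1] == 0:
            warnings.warn("treatment profile empty after selection; skipped")
        else:
            designs["treatment"] = Xt
    if "life_quality" in config.profiles:
        designs["life_quality"] = life_quality_design(cohort, config.cci_weights)

    rows = []
    for profile, X in designs.items():
        for model in config.models:
            res = cross_validate(X, y, model, k=config.folds, seed=config.seed)
            rows.append({"profile": profile, **_row(width, model, res, X.shape[1])})
    table = pd.DataFrame(rows)
    # best model per profile: accuracy, ties by AUC then model-name order
    best = (
        table.sort_values(
            ["profile", "accuracy_pct", "auc", "model"],
            ascending=[True, False, False, True],
            kind="stable",
        )
        .groupby("profile", sort=True)
        .head(1)
        .reset_index(drop=True)
    )
    return table, best


@dataclass
class SequenceAblationResult:
    """Timed-vs-untimed comparison on shared folds."""

    summary: pd.DataFrame
    #: arm name ("untimed" or "timed_w{width}") -> model method -> CVResult
    results: dict[str, dict[str, CVResult]]


def run_sequence_ablation(
    cohort: list[PatientRecord], config: ExperimentConfig
) -> SequenceAblationResult:
    """Compare the untimed baseline with the timed pipeline at each width.

    Both arms join the clinical and life-quality profiles, differ only in
    the treatment representation, and share identical stratified folds
    (asserted via the fold signature).
    """
    y = labels_of(cohort)
    clin = clinical_design(cohort)
    lq = life_quality_design(cohort, config.cci_weights)
    arms: dict[str, pd.DataFrame] = {"untimed": _join([clin, lq, untimed_design(cohort)])}
    for width in config.widths:
        Xt, _ = treatment_design(cohort, width, config.minsup, config.horizon_months)
        parts = [clin, lq] + ([Xt] if Xt.shape[1] else [])
        arms[f"timed_w{width}"] = _join(parts)

    rows, results = [], {}
    signature = None
    for arm, X in arms.items():
        results[arm] = {}
        for model in config.models:
            res = cross_validate(X, y, model, k=config.folds, seed=config.seed)
            if signature is None:
                signature = res.fold_signature
            assert res.fold_signature == signature, "arms must share identical folds"
            results[arm][model.method] = res
            rows.append({"arm": arm, **_row(None, model, res, X.shape[1])})
    return SequenceAblationResult(summary=pd.DataFrame(rows), results=results)


class TTestResult(NamedTuple):
    t: float
    p: float
    significant: bool


def paired_t_test(
    accuracies_a,
    accuracies_b,
    alpha: float = 0.05,
    one_sided: bool = True,
) -> TTestResult:
    """Paired t-test over fold accuracies; one-sided alternative "a > b".

    Identical vectors return t = 0, p = 0.5 (one-sided); zero variance with
    a nonzero mean difference is degenerate and raises.
    """
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors of length >= 2")
    d = a - b
    if np.all(d == 0):
        return TTestResult(0.0, 0.5 if one_sided else 1.0, False)
    if d.std(ddof=1) == 0:
        raise ValueError("zero variance of fold differences; t-test degenerate")
    alternative = "greater" if one_sided else "two-sided"
    res = stats.ttest_rel(a, b, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.pvalue), bool(res.pvalue < alpha))
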