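# ovsurv

Treatment-sequence mining and ensemble survival classification for advanced
ovarian cancer cohorts.

Patients with FIGO stage 3a–4 ovarian carcinoma receive several lines of
therapy — surgery, chemotherapy, neoadjuvant chemotherapy (NACT),
cytoreductive surgery (CRS), hormonal therapy — and both the *order* of those
treatments and the *time elapsed between them* carry prognostic information
that a plain "which treatments did she receive" encoding discards.  `ovsurv`
implements an integrated 3-year survival classification pipeline for such
cohorts, aimed at clinical data-mining researchers who want a tested,
reproducible reference implementation:

1. **Synthetic cohorts** (`ovsurv.cohort`) — clinical attributes (age, CA-125,
   ascites, grade, FIGO substage, histology), comorbidity flags, ECOG status
   and multi-line treatment event logs over a 36-month horizon, with survival
   labels drawn from a logistic model with plantable effects (so every
   downstream stage is testable without patient data).
2. **Cleaning and imputation** (`ovsurv.prep`) — drop patients with missing
   survival labels or >50 % missing clinical fields; fill the rest with
   class-conditional mean (numeric) / mode (nominal) imputation.
3. **No-gap sequence mining** (`ovsurv.mining`) — a modified GSP that mines
   frequent *contiguous* treatment substrings: a pattern X→Y only matches when
   no other treatment intervenes.  Support is the fraction of patients whose
   sequence contains the run; a pattern is frequent at support ≥ `minsup`
   (default 0.05).  A brute-force enumerator serves as an oracle.
4. **Time-interval features** (`ovsurv.features`) — each frequent pair (X, Y)
   expands into binary columns `X_Tk_Y`: treatment Y immediately followed X
   with the gap in the k-th bin of width *w* months (w = 1…6 over the
   36-month horizon, so 36/18/12/… bins).  Columns are then filtered by
   information gain, Gain(A) = H(D) − Σ_v |D_v|/|D| · H(D_v), keeping
   Gain > 0.
5. **Life quality** (`ovsurv.comorbidity`) — Charlson Comorbidity Index from
   the comorbidity flags (COPD +1, uncomplicated diabetes +1, end-organ
   diabetes +3, malignancy base +2 for every patient), paired with ECOG.
6. **Classification** (`ovsurv.classify`, `ovsurv.boosting`) — stratified
   10-fold CV of bagging, AdaBoost (implemented in-repo from the
   error/vote/reweight recursion: e = Σ wᵢ over misclassified instances,
   vote = log((1−e)/e), correct weights × e/(1−e), renormalise), random
   forest, gradient boosting and logistic regression; accuracy, sensitivity,
   specificity and rank-statistic AUC on pooled out-of-fold predictions.
7. **Experiments** (`ovsurv.study`) — bin-width sweep, per-profile ablation
   (clinical vs treatment vs life quality), timed vs untimed comparison on
   shared folds, and a paired one-sided t-test over fold accuracies.

## Worked example

```python
import pandas as pd
from ovsurv import *
from ovsurv.study import (
    clinical_design, life_quality_design, labels_of, treatment_design,
)

spec = CohortSpec(
    n_patients=140, seed=7,
    planted_pattern=PlantedPattern("Chemotherapy", "CRS", 4.0, 6.0, 2.0),
)
cohort = generate_cohort(spec)
print(summarize(cohort).overall_survival_rate_pct)   # 44.29

db = build_sequence_db(cohort)
for p in mine_frequent_substrings(db, minsup=0.05):
    if len(p.symbols) == 2:
        print(" -> ".join(p.symbols), p.support_count, round(p.relative_support, 3))
# Chemotherapy -> CRS 40 0.286
# Surgery -> Chemotherapy 40 0.286
# NACT -> Surgery 29 0.207 ...

Xt, report = treatment_design(cohort, width=2)        # timed, IG-selected
print(report.head(2))
#               feature  information_gain
#       NACT_T4_Surgery          0.037264
#   Chemotherapy_T3_CRS          0.036626

X = pd.concat([clinical_design(cohort), life_quality_design(cohort), Xt], axis=1)
res = cross_validate(X, labels_of(cohort), ModelSpec("adaboost"), k=10, seed=7)
print(f"{res.accuracy_pct:.1f}% acc, AUC {res.auc:.2f}")
# 56.4% acc, AUC 0.59
```

The cohort has a 44.29 % empirical 3-year survival rate (the generator is
calibrated to 42.14 %).  Mining recovers the familiar clinical transitions
(chemotherapy followed directly by interval cytoreductive surgery, primary
surgery followed by chemotherapy, NACT then surgery), and the planted timed
transition — chemotherapy→CRS with a 4–6-month gap, i.e. column
`Chemotherapy_T3_CRS` at 2-month bins — ranks near the top of the
information-gain report.  At n = 140 the boosted ensemble's out-of-fold
accuracy (56.4 %) sits modestly above the majority-class rate; the planted
signal becomes reliably recoverable at larger cohort sizes (see the test
suite's n = 600 recovery checks).

A command-line interface covers the same pipeline:

```sh
ovsurv generate --n 140 --seed 7 --out data/
ovsurv clean --in data/ --out cleaned/
ovsurv mine --in cleaned/ --minsup 0.05 --out patterns.json
ovsurv featurize --in cleaned/ --width 2 --out features/
ovsurv classify --features features/features.csv --model adaboost
ovsurv study --in cleaned/ --widths 2,6 --out results/
```

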