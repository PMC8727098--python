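# Methods

## The prediction problem

The pipeline classifies advanced (FIGO 3a–4) ovarian cancer patients into
3-year survived / deceased from three attribute profiles: clinical (age,
CA-125, ascites, grade, substage, histology), treatment (multi-line therapy
sequences with inter-treatment times), and life quality (Charlson
Comorbidity Index and ECOG performance status).  The design premise is that
*which* treatments a patient received, *in what order*, and *how quickly one
followed another* all carry prognostic signal beyond treatment presence
alone.  The package's experiments make that premise testable: a bin-width
sweep, a per-profile ablation, a timed-versus-untimed comparison on shared
folds, and a paired significance test.

## Synthetic cohort model

Real cohorts of this kind are small, single-centre and private, so the
package ships a generator whose defaults encode the study conditions the
pipeline assumes:

* **Size and outcome.** Default 140 patients, 3-year survival prevalence
  0.4214, follow-up horizon 36 months, at most 4 treatment lines.
* **Clinical marginals.** Age: uniform mixture (75 % on 40–70, 25 % on the
  full 17–80 range; median ≈ 54 years).  CA-125: lognormal around a median
  of 929.13 U/ml (σ = 1.4 on the log scale), clipped to 8.7–16301.  Ascites
  yes with probability 114/140.  Grade 2–4 (median 3), substage 3a–4
  (median 4), histology dominated by serous carcinoma (111/140).  Only
  ranges and medians of the emulated population are published; the
  distribution shapes are modelling choices.
* **Comorbidities and ECOG.** Independent Bernoulli flags (hypertension 25 %,
  CAD 10 %, COPD 8 %, …) plus a three-way diabetes category (none / 15 %
  uncomplicated / 5 % end-organ) so the two diabetes severities stay
  mutually exclusive.  The implied CCI lies almost entirely in the published
  2–9 range with median 3.  ECOG 1–5 with median 2.
* **Treatment grammar.** Sequences follow a first-order Markov chain over
  {Surgery, Chemotherapy, NACT, CRS, HormonalTherapy} whose transition mass
  covers the seven clinically familiar pairs (surgery→chemo, NACT→surgery,
  chemo→CRS, …), with 1–4 lines (mean ≈ 2.6).  Inter-treatment gaps are
  lognormal with median 6 months (σ = 0.6 log-months), matching the
  observation that most patients start the next line within 6–8 months;
  events past the horizon are truncated.  Months are real-valued
  (1 month = 30 days for any day-count conversion).
* **Outcome model.** Survival labels are Bernoulli draws from
  logit(p) = c + Σ βₐ·z(a) + β_pattern·1[carrier], where z(a) are
  empirically standardised attributes, the default effects are negative for
  age (−0.4), ECOG (−0.9) and CCI (−0.7), and an optional *planted pattern*
  (source, target, gap interval, log-odds weight) marks patients in whom the
  target treatment immediately followed the source with a gap in the stated
  interval.  The intercept c is calibrated by bisection so the cohort mean
  of p matches the requested prevalence (verified to ±0.02 over 20 seeds at
  n = 1000).
* **Reproducibility.** One integer seed drives a `SeedSequence` root split
  into one stream per patient plus a label stream; identical spec + seed
  yields byte-identical cohorts.
* **Missingness.** Optional MCAR masking of clinical cells and labels at
  configurable rates; treatment events are never masked.

What the generator does *not* emulate: joint dependence among clinical
attributes beyond the outcome model, treatment choice conditioned on
clinical state (therapy is independent of covariates unless planted),
time-to-event structure (the label is binary by design), measurement error,
or informative missingness.  Passing tests therefore demonstrate that the
pipeline recovers effects *of the kind it assumes*, not that it would
perform equivalently on hospital data.

### The planted recovery condition

The default recovery experiments plant chemotherapy→CRS with gap in
(4, 6] months and log-odds +2 — column `Chemotherapy_T3_CRS` at 2-month
bins.  The interval sits just under the median gap so roughly a quarter of
adjacent chemo→CRS transitions (≈ 7 % of patients) carry it; the weight is
strong but clinically plausible (odds ratio ≈ 7).  Recovery is asserted at
n = 600: the planted column is IG-selected and the timed pipeline beats the
untimed baseline in most seeds with the boosted ensemble.

## Cleaning and imputation

Patients lacking a survival label are removed, then patients missing
strictly more than half of the six clinical fields.  The >50 % rule is
counted over clinical attributes only, with strict inequality (a patient
missing exactly 3 of 6 is kept) — the boundary had to be fixed somewhere
and is tested explicitly.  Remaining gaps are filled class-conditionally:
numeric fields (age, CA-125) with the mean over same-label patients,
nominal fields (ascites, grade, stage, histology) with the same-label mode.
Mode ties break to the lexicographically smallest category; a class with no
observed values for a field falls back to the overall statistic.  Both
events are recorded in the cleaning report.  Imputation is idempotent and
never alters observed cells (property-tested on fuzzed cohorts).  No
outlier deletion is performed by default: no principled threshold exists
for these attributes, so the package does not invent one.

## No-gap GSP

Patterns are contiguous runs: X→Y does not match a patient who received W
between X and Y.  Mining is level-wise — frequent single symbols, then
candidates of length k+1 joining frequent k-patterns whose (k−1)-suffix and
prefix agree; for substrings the Apriori prune is implicit in the join.
Support counts each patient once regardless of repeated occurrences, and
|DB| includes patients with empty sequences, so relative support is cohort
prevalence.  "Frequent" means support_count ≥ ceil(minsup·|DB|) (the
"at least" reading), computed with a 1e−9 slack so float artifacts such as
0.05·140 = 7.000…001 do not shift the threshold.  The default minimum
support is 0.05.  A guarded brute-force enumerator over all symbol tuples
is the oracle; GSP must set-equal it on fuzzed databases.

## Time bins and information gain

Bins are half-open on the left, ((k−1)w, kw], with gap 0 assigned to T1 —
"within one month" means the whole first month.  Gaps beyond the horizon
fire no feature.  When the width does not divide the horizon (5-month bins
over 36 months) the final bin is truncated; for widths 1/2/3 the scheme
gives the expected 36/18/12 bins.  Only length-2 frequent patterns generate
timed columns (selected attributes in this design are always transition
pairs), and a pair recurring in one patient with different gaps sets every
matching bin column.  All-zero columns are dropped; order is deterministic.

Information gain uses base-2 entropy with 0·log 0 = 0; selection keeps
columns with gain > 0 (+1e−12 guard).  Two modes exist:

* **full-dataset selection** (default, mirroring the original protocol):
  gains computed once on all patients before cross-validation;
* **per-fold selection** (`FoldwiseIGSelector` in a pipeline): selection
  refitted inside each training split.

The full-dataset mode leaks label information into the folds.  The effect
is measurable: in null experiments (no planted effects) the timed arm's
leaked optimism inflates the one-sided timed-vs-untimed significance rate
above the nominal level, while the per-fold mode restores calibration.
Methodological comparisons in the test suite therefore use the per-fold
mode; recovery experiments keep the original full-dataset protocol.

## Charlson Comorbidity Index

Score = malignancy base (+2 for every patient of this cohort, toggleable)
plus the weight of each flagged condition: 1 for MI, CHF, PVD, CVD,
dementia, COPD, connective-tissue disease, ulcer, mild liver disease and
uncomplicated diabetes; 2 for hemiplegia and renal disease; 3 for
end-organ diabetes (the value used here; the classic table gives 2 — the
table is config-overridable).  The two diabetes severities are mutually
exclusive (the severer wins).  CAD is scored 1 with the ischaemic-heart
class; hypertension, which has no Charlson weight, scores 0.  No age
adjustment is applied — age is a separate clinical attribute.  The score is
monotone in the flag set (property-tested).

## Classifiers and evaluation

AdaBoost is implemented in-repo: discrete two-class boosting over
weight-fitted decision trees limited to `max_splits` internal splits
(`max_leaf_nodes = max_splits + 1`).  Per round: weighted error e, vote
log((1−e)/e) scaled by the learning rate, correct-instance weights × e/(1−e),
renormalise.  Numerical edges: e = 0 is clamped to 1e−10 (finite vote,
boosting stops — nothing is left to reweight); a round with e ≥ 0.5 is
discarded, the weights are re-drawn once from a flat Dirichlet, and
boosting stops if the retry also fails.  Scores are the logistic transform
of the additive margin.

The remaining suite delegates to scikit-learn with the study's settings:
bagging over 139-split trees (the "learning rate" sometimes listed for
bagging is meaningless and ignored), random forest with pinned seed 0 and
unlimited depth, 100-tree gradient boosting, logistic regression.

Cross-validation is stratified 10-fold by default (plain k-fold available);
stratification guards against single-class training folds at n = 140,
where each fold holds 14 patients.  Metrics come from pooled out-of-fold
predictions — stabler than averaging per-fold AUCs over 14-patient folds —
with "survived" as the positive class: accuracy in %, sensitivity
TP/(TP+FN), specificity TN/(TN+FP), and AUC as the Mann–Whitney rank
statistic with half-credit for ties (equal to the trapezoidal ROC area,
cross-checked against scikit-learn in the tests).

## Experiments and significance

The interval sweep joins clinical + life-quality + IG-selected timed
features at each width and cross-validates every model; the profile
ablation evaluates each profile alone (best model per profile by accuracy,
ties by AUC then name); the sequence ablation compares the untimed
treatments-ever-received baseline against the timed pipeline on *identical*
folds, asserted via a fold-signature check.  The paired t-test runs over
the k fold accuracies of the two arms (the only replicates available),
one-sided for "timed > untimed", df = k−1.  Identical vectors return
t = 0, p = 0.5; zero variance with nonzero mean raises rather than
fabricating a p-value.  Fold-paired CV t-tests are known to be somewhat
anti-conservative because training sets overlap; the null-calibration test
budgets for this (≤ 10 % empirical rate at α = 0.05 over 100 replicates).

## Problem sizes used in the test suite

Unit and property tests run on cohorts of 20–300 patients; the planted
recovery experiment uses 10 cohorts of n = 600 (where a ~7 % carrier
subgroup is reliably detectable); null calibration uses one n = 500 cohort
for the accuracy band and 100 cohorts of n = 150 for the type-I rate; the
generator calibration check averages 20 cohorts of n = 1000.  These sizes
were chosen as the smallest at which the tested effects are stable across
seeds.

## Known limitations

* Synthetic validation only; no claim of equivalence with results computed
  on private hospital data, and no attempt to reproduce a particular
  cohort's joint distribution beyond published marginals.
* The binary 3-year label discards censoring and event times; no
  time-to-event modelling.
* The AdaBoost variant is the classic discrete recursion; other toolchains'
  boosting implementations (surrogate splits, different shrinkage
  schedules) will not match prediction-for-prediction.
* Full-dataset IG selection is retained as the default for fidelity despite
  its measurable leakage; methodological users should prefer the per-fold
  mode.
* No class rebalancing, probability calibration, or hyperparameter search
  beyond the published settings.
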