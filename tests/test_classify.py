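"""Evaluation metrics and stratified cross-validation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from ovsurv import CohortSpec, ModelSpec, cross_validate, generate_cohort, metrics
from ovsurv.classify import default_model_specs, make_classifier
from ovsurv.study import clinical_design, labels_of


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0, 1])
        m = metrics(y, y.astype(float), y)
        assert m.accuracy_pct == 100.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0 and m.auc == 1.0

    def test_constant_scores_give_auc_half(self):
        y = np.array([1, 0, 1, 0])
        m = metrics(np.ones(4), np.full(4, 0.3), y)
        assert m.auc == pytest.approx(0.5)

    def test_confusion_matrix_arithmetic(self):
        # TP=47 FN=12 TN=60 FP=21
        y = np.array([1] * 59 + [0] * 81)
        pred = np.array([1] * 47 + [0] * 12 + [0] * 60 + [1] * 21)
        scores = pred.astype(float)
        m = metrics(pred, scores, y)
        assert m.accuracy_pct == pytest.approx(76.43, abs=0.01)
        assert m.sensitivity == pytest.approx(0.797, abs=0.001)
        assert m.specificity == pytest.approx(0.741, abs=0.001)

    def test_rank_auc_matches_trapezoidal_roc(self, rng):
        y = rng.integers(0, 2, 300)
        scores = rng.normal(size=300) + y  # informative with ties unlikely
        m = metrics((scores > 0.5).astype(int), scores, y)
        assert m.auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)
        # with heavy ties (half-credit convention)
        coarse = np.round(scores)
        m2 = metrics((coarse > 0).astype(int), coarse, y)
        assert m2.auc == pytest.approx(roc_auc_score(y, coarse), abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 100)
        s = rng.random(100)
        pred = (s > 0.5).astype(int)
        a1 = metrics(pred, s, y).auc
        a2 = metrics(pred, np.exp(5 * s), y).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="AUC"):
            metrics(np.ones(4), np.ones(4), np.ones(4))


class TestCrossValidate:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort_140():
        cohort = generate_cohort(CohortSpec(n_patients=140, seed=21))
        return clinical_design(cohort), labels_of(cohort)

    def test_fold_sizes_14_each(self, cohort_140):
        X, y = cohort_140
        res = cross_validate(X, y, ModelSpec("logistic"), k=10, seed=0)
        sizes = np.bincount(res.fold_assignments)
        assert (sizes == 14).all()

    def test_each_patient_predicted_once_and_confusion_sums_to_n(self, cohort_140):
        X, y = cohort_140
        res = cross_validate(X, y, ModelSpec("logistic"), k=10, seed=0)
        assert len(res.predictions) == len(y)
        tp = ((res.predictions == 1) & (y == 1)).sum()
        tn = ((res.predictions == 0) & (y == 0)).sum()
        fp = ((res.predictions == 1) & (y == 0)).sum()
        fn = ((res.predictions == 0) & (y == 1)).sum()
        assert tp + tn + fp + fn == len(y)

    def test_pooled_metrics_match_fold_recount(self, cohort_140):
        # independent recount from the stored per-fold assignments
        X, y = cohort_140
        res = cross_validate(X, y, ModelSpec("random_forest"), k=10, seed=0)
        correct = 0
        for fold in range(10):
            mask = res.fold_assignments == fold
            n_correct = (res.predictions[mask] == res.labels[mask]).sum()
            assert n_correct / mask.sum() == pytest.approx(res.fold_accuracies[fold])
            correct += n_correct
        assert res.accuracy_pct == pytest.approx(100 * correct / len(y))

    def test_stratified_fold_class_balance(self, cohort_140):
        X, y = cohort_140
        res = cross_validate(X, y, ModelSpec("logistic"), k=10, seed=0)
        pos_per_fold = [
            (np.asarray(y)[res.fold_assignments == f] == 1).sum() for f in range(10)
        ]
        assert max(pos_per_fold) - min(pos_per_fold) <= 1

    def test_class_smaller_than_k_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        y = np.array([1] * 5 + [0] * 15)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(X, y, ModelSpec("logistic"), k=10)

    def test_null_features_accuracy_in_binomial_band(self):
        # balanced labels independent of features
        r = np.random.default_rng(123)
        X = r.integers(0, 2, size=(500, 8)).astype(float)
        y = np.repeat([0, 1], 250)
        res = cross_validate(X, y, ModelSpec("logistic"), k=10, seed=1)
        assert 0.42 <= res.accuracy_pct / 100 <= 0.58

    def test_label_permutation_destroys_signal(self):
        import pandas as pd

        from ovsurv.study import life_quality_design

        cohort = generate_cohort(CohortSpec(n_patients=300, seed=30, survival_prevalence=0.5))
        X = pd.concat([clinical_design(cohort), life_quality_design(cohort)], axis=1)
        y = labels_of(cohort)
        informative = cross_validate(X, y, ModelSpec("logistic"), k=10, seed=0)
        permuted = np.random.default_rng(1).permutation(np.asarray(y))
        null = cross_validate(X, permuted, ModelSpec("logistic"), k=10, seed=0)
        assert informative.accuracy_pct > 55.0
        assert 42.0 <= null.accuracy_pct <= 58.0


class TestModelSuite:
    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("svm")

    def test_default_suite_mirrors_study_settings(self):
        by_name = {s.method: s for s in default_model_specs()}
        assert set(by_name) == {
            "bagging",
            "adaboost",
            "random_forest",
            "gradient_boosting",
            "logistic",
        }
        assert by_name["bagging"].hyperparameters["max_splits"] == 139
        assert by_name["adaboost"].hyperparameters == {"max_splits": 20, "learning_rate": 0.1}
        assert by_name["random_forest"].hyperparameters["seed"] == 0
        assert by_name["gradient_boosting"].hyperparameters["n_estimators"] == 100

    def test_every_model_fits_and_scores(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] > 0).astype(int)
        for spec in default_model_specs():
            est = make_classifier(spec, seed=0)
            est.fit(X, y)
            assert est.predict(X).shape == (60,)
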