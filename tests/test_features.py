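"""Time-binned transition features and information-gain selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ovsurv import (
    BinScheme,
    FeatureMatrix,
    InfoGainSelector,
    bin_index,
    build_sequence_db,
    build_timed_matrix,
    build_untimed_matrix,
    entropy,
    info_gain,
    mine_frequent_substrings,
    select_by_ig,
)
from ovsurv.mining import Pattern

from conftest import make_patient

import pandas as pd


def pattern(*symbols):
    return Pattern(symbols=tuple(symbols), support_count=1, relative_support=0.5)


class TestBinScheme:
    @pytest.mark.parametrize("width,n_bins", [(1, 36), (2, 18), (3, 12), (6, 6)])
    def test_bin_counts(self, width, n_bins):
        assert BinScheme(width, 36).n_bins == n_bins

    def test_ragged_width_truncates_final_bin(self):
        assert BinScheme(5, 36).n_bins == 8
        assert bin_index(36.0, BinScheme(5, 36)) == 8

    def test_width_beyond_horizon_rejected(self):
        with pytest.raises(ValueError):
            BinScheme(40, 36)

    @pytest.mark.parametrize(
        "gap,width,expected",
        [
            (0.5, 1, 1),  # within the first month -> T1
            (0.0, 3, 1),  # simultaneous start -> T1
            (35.9, 2, 18),
            (2.0, 2, 1),  # bin edges belong to the lower bin
            (2.0001, 2, 2),
        ],
    )
    def test_bin_index(self, gap, width, expected):
        assert bin_index(gap, BinScheme(width, 36)) == expected

    def test_gap_past_horizon_no_bin(self):
        assert bin_index(37.0, BinScheme(2, 36)) is None

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            bin_index(-0.1, BinScheme(2, 36))


class TestTimedMatrix:
    def test_gap_lands_in_named_bin(self):
        cohort = [make_patient("A", events=[("Chemotherapy", 0.0), ("CRS", 9.0)])]
        db = build_sequence_db(cohort, alphabet=("Chemotherapy", "CRS"))
        fm = build_timed_matrix(db, [pattern("Chemotherapy", "CRS")], BinScheme(2, 36))
        assert list(fm.X.columns) == ["Chemotherapy_T5_CRS"]  # ceil(9/2) = 5
        assert fm.X.loc["A", "Chemotherapy_T5_CRS"] == 1

    def test_intervening_treatment_never_fires(self):
        cohort = [
            make_patient("A", events=[("NACT", 0.0), ("Surgery", 3.0), ("CRS", 6.0)])
        ]
        db = build_sequence_db(cohort)
        fm = build_timed_matrix(db, [pattern("NACT", "CRS")], BinScheme(2, 36))
        assert fm.X.shape[1] == 0

    def test_only_pairs_generate_columns(self):
        cohort = [make_patient("A", events=[("NACT", 0.0), ("Surgery", 3.0)])]
        db = build_sequence_db(cohort, alphabet=("NACT", "Surgery", "CRS"))
        pats = [pattern("NACT"), pattern("NACT", "Surgery"), pattern("NACT", "Surgery", "CRS")]
        fm = build_timed_matrix(db, pats, BinScheme(2, 36))
        assert list(fm.X.columns) == ["NACT_T2_Surgery"]

    def test_recurring_pair_sets_both_bins(self):
        events = [("Surgery", 0.0), ("Chemotherapy", 1.0), ("Surgery", 8.0), ("Chemotherapy", 17.0)]
        db = build_sequence_db([make_patient("A", events=events)])
        fm = build_timed_matrix(db, [pattern("Surgery", "Chemotherapy")], BinScheme(2, 36))
        assert sorted(fm.X.columns) == ["Surgery_T1_Chemotherapy", "Surgery_T5_Chemotherapy"]
        assert fm.X.loc["A"].sum() == 2

    def test_single_occurrence_row_sums_at_most_one(self, small_cohort):
        db = build_sequence_db(small_cohort)
        pats = mine_frequent_substrings(db, 0.05)
        fm = build_timed_matrix(db, pats, BinScheme(2, 36))
        pairs = {tuple(p.symbols) for p in pats if len(p.symbols) == 2}
        for x, y in pairs:
            cols = [c for c in fm.X.columns if c.startswith(f"{x}_T") and c.endswith(f"_{y}")]
            for pid in fm.X.index:
                seq = db.symbols(pid)
                n_adj = sum(1 for a, b in zip(seq, seq[1:]) if (a, b) == (x, y))
                if n_adj <= 1:
                    assert fm.X.loc[pid, cols].sum() <= 1

    def test_collapsed_bins_equal_adjacency_indicator(self, small_cohort):
        db = build_sequence_db(small_cohort)
        pats = mine_frequent_substrings(db, 0.05)
        fm = build_timed_matrix(db, pats, BinScheme(36, 36))
        for col in fm.X.columns:
            x, _, y = col.split("_")
            for pid in fm.X.index:
                seq = db.symbols(pid)
                ever = any((a, b) == (x, y) for a, b in zip(seq, seq[1:]))
                assert fm.X.loc[pid, col] == int(ever)

    def test_symbol_outside_alphabet_rejected(self, small_cohort):
        db = build_sequence_db(small_cohort)
        with pytest.raises(ValueError, match="alphabet"):
            build_timed_matrix(db, [pattern("Radiation", "CRS")], BinScheme(2, 36))


class TestUntimedMatrix:
    def test_presence_only(self):
        cohort = [
            make_patient("A", events=[("NACT", 0.0), ("Surgery", 4.0)]),
            make_patient("B", events=[]),
        ]
        db = build_sequence_db(cohort, alphabet=("NACT", "Surgery", "CRS"))
        fm = build_untimed_matrix(db)
        assert fm.X.loc["A"].to_dict() == {"NACT": 1, "Surgery": 1, "CRS": 0}
        assert fm.X.loc["B"].sum() == 0

    def test_order_invariant(self):
        a = build_sequence_db(
            [make_patient("A", events=[("Surgery", 0.0), ("NACT", 5.0)])],
            alphabet=("NACT", "Surgery"),
        )
        b = build_sequence_db(
            [make_patient("A", events=[("NACT", 0.0), ("Surgery", 5.0)])],
            alphabet=("NACT", "Surgery"),
        )
        assert build_untimed_matrix(a).X.equals(build_untimed_matrix(b).X)


class TestInfoGain:
    def test_entropy_values(self):
        assert entropy([0, 1, 0, 1]) == pytest.approx(1.0)
        assert entropy([1, 1, 1]) == 0.0
        # 59 survivors / 81 deceased of 140, frozen from direct evaluation
        # of -sum p_i log2 p_i at p = 59/140, 81/140
        labels = [1] * 59 + [0] * 81
        assert entropy(labels) == pytest.approx(0.9821131, abs=1e-6)

    def test_gain_of_label_itself_is_entropy(self, rng):
        y = rng.integers(0, 2, 200)
        assert info_gain(y, y) == pytest.approx(entropy(y))

    def test_gain_of_constant_is_zero(self, rng):
        y = rng.integers(0, 2, 100)
        assert info_gain(np.ones(100), y) == pytest.approx(0.0, abs=1e-12)

    def test_independent_feature_zero_gain(self):
        assert info_gain([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            info_gain([1, 0], [1, 0, 1])

    @given(st.integers(0, 1000))
    def test_gain_bounded_by_entropy(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 60))
        col, y = r.integers(0, 2, n), r.integers(0, 2, n)
        g = info_gain(col, y)
        assert -1e-12 <= g <= entropy(y) + 1e-12


class TestSelection:
    @staticmethod
    def contingency_gain(col, y):
        """Independent route: gain from the 2x2 contingency table."""
        col, y = np.asarray(col), np.asarray(y)
        n = len(y)

        def h(p):
            p = p[p > 0]
            return float(-(p * np.log2(p)).sum())

        total = h(np.bincount(y, minlength=2) / n)
        cond = 0.0
        for v in (0, 1):
            m = col == v
            if m.any():
                cond += m.mean() * h(np.bincount(y[m], minlength=2) / m.sum())
        return total - cond

    def test_matches_contingency_arithmetic(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 80))
            col, y = rng.integers(0, 2, n), rng.integers(0, 2, n)
            assert info_gain(col, y) == pytest.approx(self.contingency_gain(col, y), abs=1e-10)

    def test_selected_set_equals_brute_force(self, rng):
        n = 60
        X = pd.DataFrame({f"f{i}": rng.integers(0, 2, n) for i in range(25)})
        y = rng.integers(0, 2, n)
        sel = InfoGainSelector().fit(X, y)
        expected = {c for c in X.columns if self.contingency_gain(X[c], y) > 1e-12}
        assert set(X.columns[sel.support_]) == expected

    def test_perfect_column_retained_with_max_gain(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        X = pd.DataFrame({"perfect": y, "noise": [1, 0, 1, 0, 0, 1]})
        fm, report = select_by_ig(FeatureMatrix(X=X, y=pd.Series(y)))
        assert "perfect" in fm.feature_names
        assert report.iloc[0].feature == "perfect"
        assert report.iloc[0].information_gain == pytest.approx(entropy(y))

    def test_all_constant_columns_warns_and_drops_all(self):
        X = pd.DataFrame({"a": [1, 1, 1, 1], "b": [0, 0, 0, 0]})
        y = pd.Series([1, 0, 1, 0])
        with pytest.warns(UserWarning, match="no features"):
            fm, _ = select_by_ig(FeatureMatrix(X=X, y=y))
        assert fm.feature_names == []

    def test_foldwise_selector_passthrough_and_selection(self):
        from ovsurv import FoldwiseIGSelector

        y = np.array([1, 1, 1, 0, 0, 0])
        X = np.column_stack(
            [
                np.linspace(0, 5, 6),  # passthrough (continuous, not a candidate)
                y,  # candidate, perfectly informative
                np.array([1, 0, 1, 1, 0, 1]),  # candidate, zero empirical gain
            ]
        ).astype(float)
        sel = FoldwiseIGSelector(candidate_mask=[False, True, True]).fit(X, y)
        assert list(sel.keep_idx_) == [0, 1]
        assert sel.transform(X).shape == (6, 2)

    def test_foldwise_selector_mask_length_checked(self):
        from ovsurv import FoldwiseIGSelector

        with pytest.raises(ValueError, match="mask"):
            FoldwiseIGSelector([True]).fit(np.zeros((4, 2)), np.array([0, 1, 0, 1]))

    def test_report_sorted_descending(self, rng):
        X = pd.DataFrame({f"f{i}": rng.integers(0, 2, 40) for i in range(8)})
        y = rng.integers(0, 2, 40)
        sel = InfoGainSelector().fit(X, y)
        gains = sel.report_.information_gain.to_numpy()
        assert (np.diff(gains) <= 1e-15).all()
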