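"""AUC, bootstrap CI, Wilcoxon rank-sum and the pooled summary AUC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from metasig import InputError, auc, auc_ci, summary_auc, wilcoxon_scores
from metasig.evaluation import evaluate_cohorts, roc_points

import oracles

scores_strategy = st.lists(
    st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=1, max_size=10
)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3, 4], [1, 2]) == 1.0

    def test_interleaved_pair_count(self):
        # pairs: (1,2) (1,4) (3,4) discordant, (3,2) concordant -> 1/4
        assert auc([1, 3], [2, 4]) == 0.25

    def test_single_tie_is_half(self):
        assert auc([2], [2]) == 0.5

    @given(scores_strategy, scores_strategy)
    def test_matches_brute_force_pair_count(self, case, control):
        assert auc(case, control) == pytest.approx(
            oracles.auc_brute(case, control), abs=1e-12
        )

    @given(scores_strategy, scores_strategy)
    def test_label_swap_complements(self, case, control):
        assert auc(case, control) + auc(control, case) == pytest.approx(1.0)

    def test_matches_sklearn_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            case = rng.normal(0.5, 1, rng.integers(2, 30))
            control = rng.normal(0, 1, rng.integers(2, 30))
            y = np.r_[np.ones(len(case)), np.zeros(len(control))]
            assert auc(case, control) == pytest.approx(
                roc_auc_score(y, np.r_[case, control]), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        case, control = rng.normal(1, 1, 15), rng.normal(0, 1, 20)
        assert auc(case, control) == pytest.approx(
            auc(np.exp(case), np.exp(control))
        )

    def test_one_class_rejected(self):
        with pytest.raises(InputError):
            auc([1.0], [])


class TestRocPoints:
    def test_endpoints_and_monotonicity(self):
        pts = roc_points([3.0, 4.0, 2.5], [1.0, 2.0])
        assert pts["fpr"].iloc[0] == 0.0 and pts["tpr"].iloc[0] == 0.0
        assert pts["fpr"].iloc[-1] == 1.0 and pts["tpr"].iloc[-1] == 1.0
        assert (pts["fpr"].diff().dropna() >= 0).all()
        assert (pts["tpr"].diff().dropna() >= 0).all()


class TestAucCi:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        case, control = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        assert auc_ci(case, control, seed=5) == auc_ci(case, control, seed=5)

    def test_perfect_separation_upper_bound_is_one(self):
        case = np.linspace(10, 11, 40)
        control = np.linspace(0, 1, 40)
        lo, hi = auc_ci(case, control, seed=0)
        assert hi == 1.0
        assert lo > 0.9

    def test_null_coverage_of_half(self):
        # identical distributions: the CI should contain 0.5 in ~95% of runs
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            case, control = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
            lo, hi = auc_ci(case, control, n_boot=500, seed=i)
            hits += lo <= 0.5 <= hi
        assert hits >= 90


class TestWilcoxon:
    def test_fully_tied_groups_give_p_one(self):
        assert wilcoxon_scores([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_exact_small_sample_perfect_separation(self):
        # 3v3 perfect separation: smallest attainable two-sided exact p = 2/20
        assert wilcoxon_scores([5, 6, 7], [1, 2, 3]) == pytest.approx(0.1)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20)[:20]:
            case = list(np.round(rng.normal(0.5, 1, 4), 2))
            control = list(np.round(rng.normal(0, 1, 4), 2))
            if len(set(case + control)) < 8:
                continue  # oracle comparison on tie-free draws
            assert wilcoxon_scores(case, control) == pytest.approx(
                oracles.wilcoxon_exact_brute(case, control), abs=1e-9
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        case, control = rng.normal(1, 1, 25), rng.normal(0, 1, 25)
        assert wilcoxon_scores(case, control) == pytest.approx(
            wilcoxon_scores(np.exp(case), np.exp(control))
        )

    def test_large_shift_significant(self):
        rng = np.random.default_rng(8)
        case, control = rng.normal(2, 1, 40), rng.normal(0, 1, 40)
        assert wilcoxon_scores(case, control) < 0.01


class TestSummaryAuc:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(
            rows, columns=["cohort_id", "auc", "n_case", "n_control", "ci_low", "ci_high"]
        )

    def test_equal_aucs_pool_to_same_value(self):
        df = self._frame([(f"C{i}", 0.9, 30, 30, 0.8, 0.96) for i in range(3)])
        s, lo, hi = summary_auc(df)
        assert s == pytest.approx(0.9, abs=1e-9)
        assert lo < 0.9 < hi

    def test_single_cohort_passthrough(self):
        df = self._frame([("C1", 0.87, 20, 25, 0.7, 0.95)])
        assert summary_auc(df) == (0.87, 0.7, 0.95)

    def test_matches_brute_force_dl_on_logit(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            k = int(rng.integers(2, 7))
            aucs = rng.uniform(0.55, 0.99, k)
            n1 = rng.integers(5, 80, k)
            n2 = rng.integers(5, 80, k)
            df = self._frame(
                [(f"C{i}", aucs[i], n1[i], n2[i], np.nan, np.nan) for i in range(k)]
            )
            got = summary_auc(df)
            want = oracles.summary_auc_brute(list(aucs), list(n1), list(n2))
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_cohort_order_invariance(self):
        rows = [("A", 0.9, 30, 30, 0, 1), ("B", 0.7, 10, 15, 0, 1), ("C", 0.8, 50, 40, 0, 1)]
        a = summary_auc(self._frame(rows))
        b = summary_auc(self._frame(rows[::-1]))
        np.testing.assert_allclose(a, b)

    def test_boundary_auc_clipped_before_logit(self):
        df = self._frame([("A", 1.0, 20, 20, 0, 1), ("B", 0.9, 20, 20, 0, 1)])
        s, lo, hi = summary_auc(df)
        assert 0.9 < s < 1.0  # finite, between the clipped inputs


class TestEvaluateCohorts:
    def test_summary_and_per_cohort_fields(self):
        rng = np.random.default_rng(12)
        tables = {}
        for cid in ["A", "B", "C"]:
            scores = np.r_[rng.normal(2, 1, 25), rng.normal(0, 1, 25)]
            tables[cid] = pd.DataFrame(
                {"class": ["case"] * 25 + ["control"] * 25, "score": scores}
            )
        roc = evaluate_cohorts(tables, n_boot=200, seed=0)
        assert len(roc.per_cohort) == 3
        assert (roc.per_cohort["ci_low"] <= roc.per_cohort["auc"]).all()
        assert (roc.per_cohort["auc"] <= roc.per_cohort["ci_high"]).all()
        assert 0.8 < roc.summary_auc <= 1.0
        assert roc.summary_ci_low <= roc.summary_auc <= roc.summary_ci_high
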