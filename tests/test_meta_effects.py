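"""Hedges' g, DerSimonian-Laird pooling, BH-FDR and the DE filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metasig import (
    InputError,
    benjamini_hochberg,
    cohort_effects,
    filter_significant,
    hedges_g,
    pool_cohort_effects,
    pool_dersimonian_laird,
)

import oracles
from conftest import make_cohort


class TestHedgesG:
    def test_hand_computed_example(self):
        g, var_g = hedges_g([2, 3, 4], [1, 2, 3])
        assert g == pytest.approx(0.8)
        # var = (n1+n2)/(n1 n2) + g^2/(2(n1+n2)) = 6/9 + 0.64/12
        assert var_g == pytest.approx(6 / 9 + 0.64 / 12)

    def test_identical_groups_give_zero(self):
        g, _ = hedges_g([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g == 0.0

    def test_swapping_groups_negates_g(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 10), rng.normal(0, 1, 12)
        g1, v1 = hedges_g(a, b)
        g2, v2 = hedges_g(b, a)
        assert g1 == pytest.approx(-g2)
        assert v1 == pytest.approx(v2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(2, 1, 8), rng.normal(0, 1, 9)
        g1, _ = hedges_g(a, b)
        g2, _ = hedges_g(3.7 * a, 3.7 * b)
        assert g1 == pytest.approx(g2)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n1, n2 = rng.integers(2, 15, 2)
            a = list(rng.normal(rng.normal(), 1 + rng.random(), n1))
            b = list(rng.normal(0, 1, n2))
            g, v = hedges_g(a, b)
            g0, v0 = oracles.hedges_g_brute(a, b)
            assert g == pytest.approx(g0, abs=1e-9)
            assert v == pytest.approx(v0, abs=1e-9)

    def test_degenerate_zero_sd_flagged_in_cohort_effects(self):
        c = make_cohort(
            [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]],
            ["case", "case", "control", "control"],
        )
        eff = cohort_effects(c)
        assert np.isnan(eff.loc["G1", "g"])
        assert np.isfinite(eff.loc["G2", "g"])


class TestDerSimonianLaird:
    def test_two_identical_cohorts(self):
        eff = pool_dersimonian_laird([(0.8, 0.1), (0.8, 0.1)])
        assert eff.Q == pytest.approx(0.0)
        assert eff.tau2 == pytest.approx(0.0)
        assert eff.mu == pytest.approx(0.8)
        assert eff.se_mu == pytest.approx(np.sqrt(0.05))

    def test_single_cohort_reduction(self):
        eff = pool_dersimonian_laird([(0.5, 0.2)])
        assert eff.mu == pytest.approx(0.5)
        assert eff.se_mu == pytest.approx(np.sqrt(0.2))
        assert eff.tau2 == 0.0 and eff.k == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            gs = list(rng.normal(0.5, 1.0, k))
            vs = list(rng.uniform(0.02, 0.5, k))
            eff = pool_dersimonian_laird(list(zip(gs, vs)))
            mu, se, tau2, q = oracles.dl_pool_brute(gs, vs)
            assert eff.mu == pytest.approx(mu, abs=1e-12)
            assert eff.se_mu == pytest.approx(se, abs=1e-12)
            assert eff.tau2 == pytest.approx(tau2, abs=1e-12)
            assert eff.Q == pytest.approx(q, abs=1e-12)

    def test_zero_tau2_equals_fixed_effect_pooling(self):
        # homogeneous effects force tau2 = 0; DL then reduces to inverse-variance
        gs, vs = [0.4, 0.4, 0.4], [0.1, 0.2, 0.05]
        eff = pool_dersimonian_laird(list(zip(gs, vs)))
        w = 1 / np.array(vs)
        assert eff.tau2 == 0.0
        assert eff.mu == pytest.approx(np.sum(w * gs) / np.sum(w))

    def test_cohort_order_invariance(self):
        pairs = [(0.3, 0.1), (0.9, 0.3), (-0.2, 0.05)]
        a = pool_dersimonian_laird(pairs)
        b = pool_dersimonian_laird(pairs[::-1])
        assert a.mu == pytest.approx(b.mu)
        assert a.tau2 == pytest.approx(b.tau2)

    def test_empty_list_raises(self):
        with pytest.raises(InputError):
            pool_dersimonian_laird([])


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        q = benjamini_hochberg([0.001, 0.02, 0.03, 0.5])
        np.testing.assert_allclose(q, [0.004, 0.04, 0.04, 0.5])

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(benjamini_hochberg([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])
        np.testing.assert_allclose(benjamini_hochberg([0.07]), [0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            benjamini_hochberg([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=12))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), oracles.bh_brute(p), atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        assert (benjamini_hochberg(p) >= p - 1e-15).all()


class TestFilterSignificant:
    @staticmethod
    def _pooled(rows):
        df = pd.DataFrame(rows, columns=["gene_id", "mu", "q"]).set_index("gene_id")
        df["se"] = 0.1
        return df

    def test_thresholds(self):
        pooled = self._pooled(
            [("A", 1.1, 0.005), ("B", 0.5, 0.005), ("C", -0.9, 0.2), ("D", -1.2, 0.001)]
        )
        kept = filter_significant(pooled)
        assert list(kept.index) == ["D", "A"]  # sorted by |mu| desc

    def test_tie_break_by_q_then_gene_id(self):
        pooled = self._pooled(
            [("B", 1.0, 0.002), ("A", 1.0, 0.002), ("C", 1.0, 0.001)]
        )
        kept = filter_significant(pooled)
        assert list(kept.index) == ["C", "A", "B"]

    def test_boundary_values_excluded(self):
        # filter is strict: q must be < fdr_max and |mu| > effect_min
        pooled = self._pooled([("A", 0.8, 0.005), ("B", 1.0, 0.01)])
        assert len(filter_significant(pooled)) == 0


class TestPoolCohortEffects:
    def test_planted_effects_recovered_across_cohorts(self):
        rng = np.random.default_rng(11)
        cohorts = [
            make_cohort(
                np.r_[
                    rng.normal(1.5, 1.0, (1, 60)),  # gene shifted in cases below
                    rng.normal(0.0, 1.0, (4, 60)),
                ],
                ["case"] * 30 + ["control"] * 30,
                cohort_id=f"C{i}",
            )
            for i in range(3)
        ]
        # shift gene 1 in cases only
        for c in cohorts:
            c.values.iloc[0, :30] += 1.0
        effects = {c.cohort_id: cohort_effects(c) for c in cohorts}
        pooled = pool_cohort_effects(effects)
        assert pooled.loc["G1", "mu"] == pytest.approx(1.0, abs=0.35)
        assert pooled.loc["G1", "q"] < 0.01
        assert (pooled.drop("G1")["q"] > 0.05).all()

    def test_gene_missing_from_one_cohort_pooled_over_available(self):
        rng = np.random.default_rng(5)
        c1 = make_cohort(rng.normal(0, 1, (2, 20)), ["case"] * 10 + ["control"] * 10, "C1")
        c2 = make_cohort(
            rng.normal(0, 1, (1, 20)),
            ["case"] * 10 + ["control"] * 10,
            "C2",
            genes=["G1"],
        )
        effects = {"C1": cohort_effects(c1), "C2": cohort_effects(c2)}
        pooled = pool_cohort_effects(effects, min_cohorts=1)
        assert pooled.loc["G1", "k"] == 2
        assert pooled.loc["G2", "k"] == 1
        # strict default drops the partial gene
        strict = pool_cohort_effects(effects)
        assert "G2" not in strict.index
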