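"""Aggression-chain statistics W(n) and T(n) against the brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rankloop.events import AggressionMatrix
from rankloop.motifs import (
    chain_scan,
    chain_statistics_suite,
    enumeration_cost,
    fractional_transitivity,
    fractional_transitivity_naive,
    weighted_rank_difference,
    weighted_rank_difference_naive,
)
from rankloop.ranking import RankOrder, ec_power, normalize_aggression

from conftest import linear_hierarchy_matrix, random_agg_matrix


def identity_order(m):
    return RankOrder(m.roster, np.arange(1, m.n + 1))


class TestClosedForms:
    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_strict_next_rank_hierarchy_gives_w_equal_n(self, n):
        m = linear_hierarchy_matrix(7, wins=2)
        w = weighted_rank_difference(m, identity_order(m), n)
        assert w.value == pytest.approx(n)
        assert w.chains_counted == 7 - n  # one chain per high-enough origin

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_equal_aggression_everywhere_gives_t_zero(self, n):
        c = 4 * (np.ones((6, 6), int) - np.eye(6, dtype=int))
        m = AggressionMatrix(c, tuple("ABCDEF"))
        for baseline in ("interior", "first"):
            t = fractional_transitivity(m, n, baseline)
            assert t.value == pytest.approx(0.0, abs=1e-12)

    def test_origin_never_attacking_terminals_gives_t_minus_one(self):
        # A->B->C is the only 2-chain; A attacks D but never C
        c = np.zeros((4, 4), int)
        c[0, 1], c[1, 2], c[0, 3] = 5, 2, 3
        m = AggressionMatrix(c, tuple("ABCD"))
        t = fractional_transitivity(m, 2)
        assert t.value == pytest.approx(-1.0)

    def test_no_positive_weight_chain_is_undefined(self):
        c = np.zeros((4, 4), int)
        c[0, 1] = 3  # no 2-step continuation anywhere
        m = AggressionMatrix(c, tuple("ABCD"))
        w = weighted_rank_difference(m, identity_order(m), 2)
        assert not w.defined


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_matrices_match_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_ind = int(rng.integers(4, 8))
        m = random_agg_matrix(rng, n_ind)
        order = ec_power(normalize_aggression(m, 0.01)).rank_order()
        for n in range(1, min(5, n_ind - 1) + 1):
            fast = weighted_rank_difference(m, order, n)
            slow = weighted_rank_difference_naive(m, order, n)
            assert fast.value == pytest.approx(slow.value, abs=1e-12)
            assert fast.total_weight == pytest.approx(slow.total_weight, rel=1e-12)
            if n >= 2:
                for baseline in ("interior", "first"):
                    tf = fractional_transitivity(m, n, baseline)
                    tn = fractional_transitivity_naive(m, n, baseline)
                    assert tf.value == pytest.approx(tn.value, abs=1e-12)

    def test_repeated_identity_chains_are_excluded(self):
        # a 2-cycle A<->B would form the walk A->B->A; with distinctness
        # enforced there is no valid 2-chain at all
        c = np.zeros((3, 3), int)
        c[0, 1] = c[1, 0] = 4
        m = AggressionMatrix(c, ("A", "B", "C"))
        w = weighted_rank_difference(m, identity_order(m), 2)
        assert w.chains_counted == 0
        assert not w.defined


class TestInvariances:
    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 1000), scale=st.integers(2, 9))
    def test_scalar_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        m = random_agg_matrix(rng, 5)
        order = identity_order(m)
        m2 = AggressionMatrix(m.counts * scale, m.roster)
        for n in (1, 2, 3):
            a = weighted_rank_difference(m, order, n)
            b = weighted_rank_difference(m2, order, n)
            if a.defined:
                assert b.value == pytest.approx(a.value, abs=1e-10)
            if n >= 2:
                ta = fractional_transitivity(m, n)
                tb = fractional_transitivity(m2, n)
                if ta.defined:
                    assert tb.value == pytest.approx(ta.value, abs=1e-10)

    def test_cost_guard_refuses_huge_enumerations(self):
        m = random_agg_matrix(np.random.default_rng(0), 21, max_count=3)
        assert enumeration_cost(21, 6) < 2_000_000_000  # the study size fits
        with pytest.raises(ValueError, match="cap"):
            chain_scan(m, None, 6, cost_cap=1_000)


class TestSuite:
    def test_null_sample_fed_as_observed_is_unremarkable(self):
        # score one null draw against the rest of its own ensemble:
        # p-values should not be extreme
        from rankloop.nullmodel import fit_null_kernel, sample_null_ensemble

        v = np.array([0.05, 0.1, 0.15, 0.2, 0.22, 0.28])
        k = fit_null_kernel(v)
        ens = sample_null_ensemble(k, [30] * 6, 80, rng=4)
        probe = ens.matrices()[0]
        rest = sample_null_ensemble(k, [30] * 6, 80, rng=5)
        order = ec_power(normalize_aggression(probe, 0.01)).rank_order()
        stats = chain_statistics_suite(probe, order, rest, max_n=3)
        for s in stats:
            if np.isfinite(s.W_p):
                assert s.W_p > 0.01
            if s.n >= 2 and np.isfinite(s.T_p):
                assert s.T_p > 0.01

    def test_suite_reports_all_lengths_and_directions(self):
        rng = np.random.default_rng(8)
        m = random_agg_matrix(rng, 6)
        order = identity_order(m)
        stats = chain_statistics_suite(m, order, None, max_n=4)
        assert [s.n for s in stats] == [1, 2, 3, 4]
        assert np.isnan(stats[0].T)  # T(1) undefined by construction
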