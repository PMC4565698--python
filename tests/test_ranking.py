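"""Power scores: EC stationary distribution, WSC, David's Score, bootstrap."""

import numpy as np
import pytest
from scipy import linalg

from rankloop.events import AggressionMatrix
from rankloop.ranking import (
    bootstrap_power,
    davids_score,
    ec_power,
    normalize_aggression,
    rank_agreement,
    wsc_power,
)

from conftest import TOY4, make_log, random_agg_matrix


class TestNormalize:
    def test_rows_sum_to_one_and_diag_zero(self, toy4_matrix):
        t = normalize_aggression(toy4_matrix, 0.01)
        np.testing.assert_allclose(t.t.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diag(t.t) == 0)

    def test_two_bird_group_is_forced(self):
        m = AggressionMatrix(np.array([[0, 1], [1, 0]]), ("A", "B"))
        t = normalize_aggression(m, 0.0)
        np.testing.assert_allclose(t.t, [[0, 1], [1, 0]])

    def test_zero_matrix_with_epsilon_is_uniform(self):
        m = AggressionMatrix(np.zeros((4, 4), int), tuple("ABCD"))
        t = normalize_aggression(m, 0.5)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(t.t[off], 1 / 3)

    def test_silent_row_with_zero_epsilon_errors(self):
        m = AggressionMatrix(np.array([[0, 1], [0, 0]]), ("A", "B"))
        with pytest.raises(ValueError, match="epsilon"):
            normalize_aggression(m, 0.0)


class TestECPower:
    def test_symmetric_uniform_aggression_gives_uniform_scores(self):
        c = 5 * (np.ones((6, 6), int) - np.eye(6, dtype=int))
        m = AggressionMatrix(c, tuple("ABCDEF"))
        v = ec_power(normalize_aggression(m, 0.01)).scores
        np.testing.assert_allclose(v, 1 / 6, atol=1e-10)

    def test_two_state_chain_is_half_half(self):
        m = AggressionMatrix(np.array([[0, 7], [2, 0]]), ("A", "B"))
        v = ec_power(normalize_aggression(m, 0.0)).scores
        np.testing.assert_allclose(v, [0.5, 0.5], atol=1e-12)

    def test_matches_dense_eigenvector_oracle(self, toy4_matrix):
        t = normalize_aggression(toy4_matrix, 0.01)
        v = ec_power(t).scores
        vals, vecs = linalg.eig(t.t.T)  # independent dense solve
        w = np.abs(np.real(vecs[:, np.argmin(np.abs(vals - 1))]))
        w /= w.sum()
        np.testing.assert_allclose(v, w, atol=1e-10)

    def test_scores_sum_to_one_and_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        m = random_agg_matrix(rng, 6)
        v = ec_power(normalize_aggression(m, 0.01)).scores
        assert v.sum() == pytest.approx(1.0)
        perm = rng.permutation(6)
        mp = AggressionMatrix(
            m.counts[np.ix_(perm, perm)], tuple(m.roster[i] for i in perm)
        )
        vp = ec_power(normalize_aggression(mp, 0.01)).scores
        np.testing.assert_allclose(vp, v[perm], atol=1e-10)

    def test_epsilon_continuity_toward_zero(self):
        # irreducible counts: epsilon-regularized stationary vector
        # converges to the epsilon=0 one
        rng = np.random.default_rng(2)
        c = rng.integers(1, 8, (5, 5))
        np.fill_diagonal(c, 0)
        m = AggressionMatrix(c, tuple("ABCDE"))
        v0 = ec_power(normalize_aggression(m, 0.0)).scores
        errs = [
            np.abs(ec_power(normalize_aggression(m, e)).scores - v0).max()
            for e in (1e-2, 1e-4, 1e-6)
        ]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 1e-6

    def test_reducible_chain_advises_epsilon(self):
        # two disconnected fighting pairs: every row is positive but the
        # chain has two closed classes
        c = np.array(
            [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]]
        )
        m = AggressionMatrix(c, ("A", "B", "C", "D"))
        with pytest.raises(ValueError, match="reducible"):
            ec_power(normalize_aggression(m, 0.0))

    def test_added_incoming_aggression_tends_to_raise_score(self):
        # EC is a global measure, so monotonicity is a tendency, not a
        # theorem: check the average effect over random perturbations.
        rng = np.random.default_rng(3)
        deltas = []
        for _ in range(50):
            m = random_agg_matrix(rng, 6, max_count=5)
            i, j = rng.choice(6, size=2, replace=False)
            v0 = ec_power(normalize_aggression(m, 0.01)).scores[j]
            c = m.counts.copy()
            c[i, j] += 3
            m2 = AggressionMatrix(c, m.roster)
            v1 = ec_power(normalize_aggression(m2, 0.01)).scores[j]
            deltas.append(v1 - v0)
        assert np.mean(deltas) > 0


class TestWSC:
    def test_hand_computed_scores_and_order(self, toy4_matrix):
        ps = wsc_power(toy4_matrix)
        # incoming totals (1, 4, 4, 4) x distinct aggressors (1, 2, 3, 1)
        np.testing.assert_array_equal(ps.scores, [1, 8, 12, 4])
        assert ps.rank_order().ids_by_rank() == ["A", "D", "B", "C"]

    def test_no_incoming_aggression_scores_zero(self):
        m = AggressionMatrix(np.array([[0, 2], [0, 0]]), ("A", "B"))
        assert wsc_power(m).scores[0] == 0
        # B: 2 events from 1 aggressor
        assert wsc_power(m).scores[1] == 2


class TestDavidsScore:
    def test_symmetric_matrix_scores_zero(self):
        c = 3 * (np.ones((4, 4), int) - np.eye(4, dtype=int))
        np.testing.assert_allclose(davids_score(AggressionMatrix(c, tuple("ABCD"))).scores, 0.0)

    def test_dyad_antisymmetry(self):
        m = AggressionMatrix(np.array([[0, 3], [1, 0]]), ("A", "B"))
        ds = davids_score(m).scores
        assert ds[0] == pytest.approx(-ds[1])
        assert ds[0] == pytest.approx(0.5)

    def test_hand_worked_four_bird_example(self, toy4_matrix):
        # frozen from the standard DS worked example on TOY4
        ds = davids_score(toy4_matrix).scores
        np.testing.assert_allclose(ds, [3.05, 0.2166667, -1.4, -1.8666667], atol=1e-6)
        # DS is zero-sum and higher DS = more dominant
        assert ds.sum() == pytest.approx(0.0)
        assert davids_score(toy4_matrix).rank_order().ids_by_rank()[0] == "A"


class TestAgreement:
    def test_identical_scorings(self, toy4_matrix):
        a = wsc_power(toy4_matrix)
        rep = rank_agreement(a, a)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.signed_r2 == pytest.approx(1.0)

    def test_reversed_scoring_gives_minus_one(self, toy4_matrix):
        from rankloop.ranking import PowerScores

        a = wsc_power(toy4_matrix)
        b = PowerScores(a.roster, -a.scores, "WSC")
        rep = rank_agreement(a, b)
        assert rep.signed_r2 == pytest.approx(-1.0)
        assert rep.spearman_rho == pytest.approx(-1.0)

    def test_constant_scoring_flagged(self, toy4_matrix):
        from rankloop.ranking import PowerScores

        a = wsc_power(toy4_matrix)
        b = PowerScores(a.roster, np.ones(4), "WSC")
        assert rank_agreement(a, b).degenerate


class TestBootstrap:
    def test_single_dyad_scores_constant(self):
        log = make_log([0.0, 100.0], ["A", "B"], ["B", "A"], roster=("A", "B"))
        df = bootstrap_power(log, n_boot=20, rng=0)
        # resampling a two-event log still leaves a two-state chain;
        # EC is (0.5, 0.5) for every replicate
        np.testing.assert_allclose(df["boot_sd"], 0.0, atol=1e-12)

    def test_same_seed_reproduces(self, toy_log):
        a = bootstrap_power(toy_log, n_boot=30, rng=7)
        b = bootstrap_power(toy_log, n_boot=30, rng=7)
        np.testing.assert_allclose(a["score_mean"], b["score_mean"])

    def test_strong_hierarchy_extreme_ranks_are_stable(self):
        # EC concentrates information where aggression lands, so the
        # bottom of a strong hierarchy is pinned almost exactly across
        # resamples while the top (which receives little aggression)
        # stays in the top quartile on average
        from rankloop.synth import GeneratorConfig, simulate_events

        log, truth = simulate_events(GeneratorConfig(phase_change_day=0.0, rng_seed=11))
        df = bootstrap_power(log, n_boot=40, rng=1).set_index("id")
        bottom = truth.roster[np.argmax(truth.latent_ranks)]
        top = truth.roster[np.argmin(truth.latent_ranks)]
        assert df.loc[bottom, "modal_rank"] == log.n_individuals
        assert df.loc[bottom, "modal_rank_freq"] > 0.5
        assert df.loc[top, "rank_mean"] <= log.n_individuals / 4
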