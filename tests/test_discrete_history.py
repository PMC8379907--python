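"""CTMC machinery: transition probabilities, conditional history sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import linalg, stats

import statedep as sd
from statedep.discrete_history import (CTMCRates, CharacterHistory,
                                       history_log_density, sample_history,
                                       transition_matrix)
from statedep.io_formats import PhyloTree, TipStateTable


class TestTransitionMatrix:
    def test_zero_time_is_identity(self):
        P = transition_matrix(CTMCRates(3.0, 0.7), 0.0)
        np.testing.assert_allclose(P, np.eye(2))

    def test_long_time_reaches_stationary(self):
        P = transition_matrix(CTMCRates(1.0, 1.0), 100.0)
        np.testing.assert_allclose(P, 0.25 + np.full((2, 2), 0.25), atol=1e-12)

    def test_asymmetric_closed_form(self):
        P = transition_matrix(CTMCRates(2.0, 1.0), 0.5)
        assert P[0, 1] == pytest.approx((2 / 3) * (1 - math.exp(-1.5)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_matrix_exponential(self, seed):
        rng = np.random.default_rng(seed)
        q01, q10 = rng.exponential(1.0, 2)
        t = rng.exponential(1.0)
        Q = np.array([[-q01, q01], [q10, -q10]])
        np.testing.assert_allclose(transition_matrix(CTMCRates(q01, q10), t),
                                   linalg.expm(Q * t), atol=1e-11)
        assert np.allclose(transition_matrix(CTMCRates(q01, q10), t).sum(axis=1), 1.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(CTMCRates(1.0, 1.0), -0.1)


def _const_history(tree, state):
    st = [np.array([state], dtype=np.int8) for _ in range(tree.n_nodes - 1)]
    du = [np.array([tree.blen[i]]) for i in range(1, tree.n_nodes)]
    return CharacterHistory(tree, np.full(tree.n_nodes, state, np.int8), st, du)


class TestHistorySummaries:
    def test_constant_history_counts(self, three_tip):
        h = _const_history(three_tip, 1)
        assert h.count_transitions() == (0, 0)
        dt = h.dwell_times()
        np.testing.assert_allclose(dt[1:, 1], three_tip.blen[1:])
        np.testing.assert_allclose(dt[1:, 0], 0.0)

    def test_segment_examples(self, single_branch):
        h = CharacterHistory(single_branch, np.array([0, 0], np.int8),
                             [np.array([0, 1, 0], np.int8)],
                             [np.array([0.3, 0.5, 0.2])])
        assert h.count_transitions() == (1, 1)
        np.testing.assert_allclose(h.dwell_times()[1], [0.5, 0.5])

    def test_invalid_histories_rejected(self, single_branch):
        with pytest.raises(ValueError, match="alternate"):
            CharacterHistory(single_branch, np.array([0, 0], np.int8),
                             [np.array([0, 0], np.int8)], [np.array([0.5, 0.5])])
        with pytest.raises(ValueError, match="sum"):
            CharacterHistory(single_branch, np.array([0, 1], np.int8),
                             [np.array([0, 1], np.int8)], [np.array([0.3, 0.3])])


class TestSampleHistory:
    def test_zero_gain_rate_gives_constant_zero(self, three_tip):
        states = TipStateTable(labels=three_tip.tip_labels, states=np.zeros(3, int))
        h = sample_history(three_tip, states, CTMCRates(0.0, 0.5), seed=1)
        assert h.count_transitions() == (0, 0)
        assert np.all(h.node_states == 0)

    def test_unreachable_configuration_raises(self, three_tip):
        states = TipStateTable(labels=three_tip.tip_labels, states=np.array([0, 1, 0]))
        with pytest.raises(ValueError, match="unreachable"):
            sample_history(three_tip, states, CTMCRates(0.0, 0.5), root_prior=0, seed=1)

    def test_seed_determinism(self, three_tip):
        states = TipStateTable(labels=three_tip.tip_labels, states=np.array([0, 1, 0]))
        h1 = sample_history(three_tip, states, CTMCRates(0.7, 0.4), seed=11)
        h2 = sample_history(three_tip, states, CTMCRates(0.7, 0.4), seed=11)
        assert h1.to_frame().equals(h2.to_frame())

    def test_sampled_histories_satisfy_invariants(self):
        rng = np.random.default_rng(0)
        tree = sd.simulate_yule(12, 1.0, rng)
        labels = tree.tip_labels
        for rep in range(50):
            states = TipStateTable(labels=labels,
                                   states=rng.integers(0, 2, len(labels)))
            try:
                h = sample_history(tree, states, CTMCRates(0.5, 0.5), seed=rep)
            except ValueError:
                continue
            h.validate()
            assert h.tip_states().states.tolist() == states.states.tolist()
            np.testing.assert_allclose(h.dwell_times()[1:].sum(axis=1),
                                       tree.blen[1:], atol=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(q01=st.floats(0.01, 3.0), q10=st.floats(0.01, 3.0),
           seed=st.integers(0, 10_000))
    def test_dwell_conservation_under_any_rates(self, q01, q10, seed):
        """Segment durations always partition each branch exactly."""
        three_tip = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        states = TipStateTable(labels=three_tip.tip_labels, states=np.array([0, 1, 0]))
        h = sample_history(three_tip, states, CTMCRates(q01, q10), seed=seed)
        h.validate()
        np.testing.assert_allclose(h.dwell_times()[1:].sum(axis=1),
                                   three_tip.blen[1:], atol=1e-9)
        ng, nl = h.count_transitions()
        # parity: net change root->each tip equals gains - losses along its path
        for tip in three_tip.tip_indices:
            node, flips = int(tip), 0
            while node != 0:
                st_, _ = h.branch(node)
                flips += len(st_) - 1
                node = int(three_tip.parent[node])
            assert (flips % 2 == 0) == (h.node_states[tip] == h.node_states[0])

    def test_conditioned_transition_counts_match_closed_form(self, single_branch):
        """0 -> 0 bridge with q01 = q10 = 1, t = 1: flips are Poisson(1)
        conditioned on an even count."""
        states = TipStateTable(labels=["A"], states=np.array([0]))
        n_draws = 4000
        sd._kernels.set_seed(123)
        counts = np.zeros(8, int)
        for _ in range(n_draws):
            h = sample_history(single_branch, states, CTMCRates(1.0, 1.0),
                               root_prior=0)
            ng, nl = h.count_transitions()
            counts[min(ng + nl, 7)] += 1
        evens = np.arange(0, 14, 2)
        pmf = np.array([1.0 / math.factorial(m) for m in evens])
        pmf /= pmf.sum()
        expected = np.zeros(8)
        expected[[0, 2, 4, 6]] = pmf[:4] * n_draws
        expected[7] = pmf[4:].sum() * n_draws
        keep = expected > 0
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert counts[[1, 3, 5]].sum() == 0  # odd flip counts are impossible
        assert p > 0.01

    def test_cherry_root_marginal_matches_pruning(self, cherry):
        """Empirical root-state frequency equals the exact conditional."""
        rates = CTMCRates(0.8, 0.5)
        states = TipStateTable(labels=["A", "B"], states=np.array([0, 1]))
        P = transition_matrix(rates, 1.0)
        pi0 = rates.stationary_p0()
        w = np.array([pi0 * P[0, 0] * P[0, 1], (1 - pi0) * P[1, 0] * P[1, 1]])
        exact_p1 = w[1] / w.sum()
        n_draws = 4000
        sd._kernels.set_seed(7)
        hits = sum(int(sample_history(cherry, states, rates).node_states[0])
                   for _ in range(n_draws))
        se = math.sqrt(exact_p1 * (1 - exact_p1) / n_draws)
        assert abs(hits / n_draws - exact_p1) < 3 * se

    def test_symmetric_relabeling_invariance(self, three_tip):
        """With q01 = q10, relabeling 0 <-> 1 leaves sampler distributions
        unchanged: compare mean transition counts and state-1 root frequency."""
        rates = CTMCRates(0.6, 0.6)
        s_a = TipStateTable(labels=three_tip.tip_labels, states=np.array([0, 1, 0]))
        s_b = TipStateTable(labels=three_tip.tip_labels, states=np.array([1, 0, 1]))
        n_draws = 3000

        def stats_for(states, seed):
            sd._kernels.set_seed(seed)
            tot, root1 = 0, 0
            for _ in range(n_draws):
                h = sample_history(three_tip, states, rates)
                ng, nl = h.count_transitions()
                tot += ng + nl
                root1 += int(h.node_states[0])
            return tot / n_draws, root1 / n_draws

        mean_a, root_a = stats_for(s_a, 21)
        mean_b, root_b = stats_for(s_b, 22)
        assert abs(mean_a - mean_b) < 0.15
        assert abs(root_a - (1 - root_b)) < 0.05


class TestHistoryDensity:
    def test_constant_branch_closed_form(self, single_branch):
        h = _const_history(single_branch, 0)
        rates = CTMCRates(0.3, 0.9)
        expect = -0.3 * 1.0 + math.log(rates.stationary_p0())
        assert history_log_density(h, rates) == pytest.approx(expect, abs=1e-12)

    def test_fixed_root_prior(self, single_branch):
        h = _const_history(single_branch, 0)
        assert history_log_density(h, CTMCRates(0.3, 0.9), root_prior=0) == \
            pytest.approx(-0.3, abs=1e-12)
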