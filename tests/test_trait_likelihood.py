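"""State-dependent BM likelihood: effective lengths and REML contrasts."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import statedep as sd
from statedep.discrete_history import CTMCRates, CharacterHistory
from statedep.io_formats import PhyloTree, TraitMatrix
from statedep.trait_likelihood import (ModelState, effective_branch_length,
                                       effective_branch_lengths,
                                       joint_log_posterior, pruning_loglik)
from conftest import dense_reml_oracle, random_tree


def _history_with_dwell(tree, node, t0, t1, state_elsewhere=0):
    """History whose branch above ``node`` dwells (t0, t1); constant elsewhere."""
    node_states = np.full(tree.n_nodes, state_elsewhere, np.int8)
    seg_s, seg_d = [], []
    for i in range(1, tree.n_nodes):
        if i == node and t1 > 0 and t0 > 0:
            seg_s.append(np.array([0, 1], np.int8))
            seg_d.append(np.array([t0, t1]))
            node_states[i] = 1
        elif i == node and t0 == 0:
            seg_s.append(np.array([1], np.int8))
            seg_d.append(np.array([t1]))
            node_states[i] = 1
        else:
            seg_s.append(np.array([state_elsewhere], np.int8))
            seg_d.append(np.array([tree.blen[i]]))
    return CharacterHistory(tree, node_states, seg_s, seg_d, validate=False)


def _state(n_nodes, sigma2=1.0, nu=0.3, beta=None, zeta=(1.0, 1.0), delta=0,
           rates=(0.5, 0.5), k=1):
    b = np.ones(n_nodes) if beta is None else beta
    return ModelState(sigma2_global=sigma2, nu=nu, beta=b, zeta=zeta,
                      delta=delta, rates=CTMCRates(*rates), Sigma=np.eye(k))


class TestEffectiveBranchLength:
    def test_state_independent_identity(self):
        tree = PhyloTree(np.array([-1, 0]), np.array([0.0, 2.0]), [None, "A"])
        h = _history_with_dwell(tree, 1, 1.0, 1.0)
        ms = _state(2, delta=0)
        assert effective_branch_length(1, ms, h) == pytest.approx(2.0)

    def test_mean_one_constraint_with_even_dwell(self):
        tree = PhyloTree(np.array([-1, 0]), np.array([0.0, 1.0]), [None, "A"])
        h = _history_with_dwell(tree, 1, 0.5, 0.5)
        ms = _state(2, delta=1, zeta=(0.5, 1.5))
        assert effective_branch_length(1, ms, h) == pytest.approx(1.0)

    def test_full_arithmetic(self):
        tree = PhyloTree(np.array([-1, 0]), np.array([0.0, 2.0]), [None, "A"])
        h = _history_with_dwell(tree, 1, 0.0, 2.0)
        beta = np.array([1.0, 0.5])
        ms = _state(2, sigma2=2.0, beta=beta, delta=1, zeta=(0.5, 1.5))
        assert effective_branch_length(1, ms, h) == pytest.approx(3.0)


class TestPruningLoglik:
    def test_cherry_closed_form(self, cherry):
        v = np.array([0.0, 1.0, 1.0])
        ll = pruning_loglik(cherry, np.array([[0.0], [0.0]]), v, np.eye(1))
        assert ll == pytest.approx(-0.5 * math.log(2 * math.pi * 2), abs=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree = random_tree(rng, 8)
            y = rng.standard_normal((8, 2))
            v = np.abs(tree.blen) + 0.1
            v[0] = 0.0
            S = np.array([[1.0, 0.3], [0.3, 1.0]])
            ll1 = pruning_loglik(tree, y, v, S)
            ll2 = pruning_loglik(tree, y + 11.5, v, S)
            assert ll1 == pytest.approx(ll2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_tips = int(rng.integers(3, 6))
        k = int(rng.integers(1, 4))
        tree = random_tree(rng, n_tips)
        y = rng.standard_normal((n_tips, k))
        v = np.concatenate([[0.0], rng.uniform(0.1, 2.0, tree.n_nodes - 1)])
        A = rng.standard_normal((k, k)) * 0.3
        S = A @ A.T + np.eye(k)
        d = np.sqrt(np.diag(S))
        S = S / np.outer(d, d)
        assert pruning_loglik(tree, y, v, S) == pytest.approx(
            dense_reml_oracle(tree, y, v, S), abs=1e-8)

    def test_polytomy_matches_dense_oracle(self):
        tree = PhyloTree.from_newick("(A:1,B:1.5,C:2,(D:0.5,E:0.5):1);")
        rng = np.random.default_rng(44)
        y = rng.standard_normal((5, 1))
        v = np.concatenate([[0.0], rng.uniform(0.2, 1.5, tree.n_nodes - 1)])
        assert pruning_loglik(tree, y, v, np.eye(1)) == pytest.approx(
            dense_reml_oracle(tree, y, v, np.eye(1)), abs=1e-8)

    def test_tip_order_permutation_invariance(self, three_tip):
        import pandas as pd
        from statedep.io_formats import _align
        y = np.array([[0.1], [1.4], [-0.7]])
        v = np.concatenate([[0.0], three_tip.blen[1:]])
        base = pruning_loglik(three_tip, y, v, np.eye(1))
        df = pd.DataFrame({"tip": ["C", "A", "B"], "size": [-0.7, 0.1, 1.4]})
        aligned = _align(df, three_tip, "mem")
        y2 = aligned[["size"]].to_numpy()
        assert pruning_loglik(three_tip, y2, v, np.eye(1)) == pytest.approx(base, abs=1e-12)

    def test_homogeneous_bm_limit(self):
        """nu -> 0 and delta = 0: plain BM; matches the dense homogeneous REML."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            tree = random_tree(rng, 6)
            y = rng.standard_normal((6, 1))
            sigma2 = rng.uniform(0.5, 2.0)
            v = sigma2 * tree.blen
            v[0] = 0.0
            assert pruning_loglik(tree, y, v, np.eye(1)) == pytest.approx(
                dense_reml_oracle(tree, y, sigma2 * tree.blen, np.eye(1)), abs=1e-8)

    def test_identity_sigma_sums_univariate(self):
        rng = np.random.default_rng(12)
        tree = random_tree(rng, 7)
        y = rng.standard_normal((7, 3))
        v = np.concatenate([[0.0], rng.uniform(0.1, 2.0, tree.n_nodes - 1)])
        joint = pruning_loglik(tree, y, v, np.eye(3))
        split = sum(pruning_loglik(tree, y[:, [j]], v, np.eye(1)) for j in range(3))
        assert joint == pytest.approx(split, abs=1e-10)

    def test_zero_depth_with_variation_is_neg_inf(self, cherry):
        v = np.zeros(3)
        with pytest.warns(UserWarning, match="zero-variance"):
            ll = pruning_loglik(cherry, np.array([[0.0], [1.0]]), v, np.eye(1))
        assert ll == -np.inf

    def test_negative_effective_length_rejected(self, cherry):
        with pytest.raises(ValueError):
            pruning_loglik(cherry, np.zeros((2, 1)), np.array([0.0, -1.0, 1.0]), np.eye(1))


class TestModelState:
    def test_mean_one_constraint_enforced(self):
        with pytest.raises(ValueError, match="mean-1"):
            _state(3, delta=1, zeta=(0.5, 1.2))

    def test_delta_zero_requires_unit_zeta(self):
        with pytest.raises(ValueError):
            _state(3, delta=0, zeta=(0.5, 1.5))

    def test_non_positive_definite_sigma_rejected(self):
        with pytest.raises(ValueError):
            ModelState(sigma2_global=1.0, nu=0.1, beta=np.ones(3), zeta=(1.0, 1.0),
                       delta=0, rates=CTMCRates(0.1, 0.1),
                       Sigma=np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestJointLogPosterior:
    def _setup(self, seed=0, n_tips=10):
        ds = sd.generate_dataset(sd.SimConfig(n_tips=n_tips, seed=seed))
        return ds

    def test_monotone_toward_conditional_sigma2_optimum(self):
        ds = self._setup()
        pri = sd.Priors()

        def lp(log_s):
            ms = ModelState(sigma2_global=math.exp(log_s), nu=ds.truth.nu,
                            beta=ds.truth.beta, zeta=ds.truth.zeta,
                            delta=ds.truth.delta, rates=ds.truth.rates,
                            Sigma=ds.truth.Sigma)
            return joint_log_posterior(ms, ds.true_history, ds.tree, ds.traits, pri)

        opt = minimize_scalar(lambda s: -lp(s), bounds=(-6, 6), method="bounded")
        start = opt.x + 2.5  # perturbed state
        grid = np.linspace(start, opt.x, 8)
        vals = [lp(s) for s in grid]
        assert all(b >= a - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_delta_toggle_changes_only_prior_when_zeta_unit(self):
        ds = self._setup(seed=2)
        pri = sd.Priors()
        ms0 = ModelState(sigma2_global=1.0, nu=0.3, beta=ds.truth.beta,
                         zeta=(1.0, 1.0), delta=0, rates=ds.truth.rates,
                         Sigma=ds.truth.Sigma)
        ms1 = ModelState(sigma2_global=1.0, nu=0.3, beta=ds.truth.beta,
                         zeta=(1.0, 1.0), delta=1, rates=ds.truth.rates,
                         Sigma=ds.truth.Sigma)
        d_joint = (joint_log_posterior(ms1, ds.true_history, ds.tree, ds.traits, pri)
                   - joint_log_posterior(ms0, ds.true_history, ds.tree, ds.traits, pri))
        d_prior = pri.log_density(ms1) - pri.log_density(ms0)
        assert d_joint == pytest.approx(d_prior, abs=1e-10)

    def test_sigma2_beta_ridge_leaves_likelihood_unchanged(self):
        ds = self._setup(seed=5)
        v1 = effective_branch_lengths(ds.truth, ds.true_history)
        doubled = ModelState(sigma2_global=2 * ds.truth.sigma2_global,
                             nu=ds.truth.nu, beta=ds.truth.beta / 2.0,
                             zeta=ds.truth.zeta, delta=ds.truth.delta,
                             rates=ds.truth.rates, Sigma=ds.truth.Sigma)
        v2 = effective_branch_lengths(doubled, ds.true_history)
        ll1 = pruning_loglik(ds.tree, ds.traits, v1, ds.truth.Sigma)
        ll2 = pruning_loglik(ds.tree, ds.traits, v2, ds.truth.Sigma)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_invariant_violation_raises(self):
        ds = self._setup(seed=6)
        ms = ds.truth
        ms.sigma2_global = -1.0
        with pytest.raises(ValueError):
            joint_log_posterior(ms, ds.true_history, ds.tree, ds.traits, sd.Priors())
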