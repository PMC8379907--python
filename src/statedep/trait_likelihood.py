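"""State-dependent Brownian-motion likelihood for continuous traits.

A trait evolves on the tree as Brownian motion whose instantaneous variance on
branch ``l`` while the lifestyle character is in state ``s`` equals

    sigma2_global * beta_l * zeta_s**delta,

with ``beta_l`` a branch-specific background multiplier (lognormal, median 1),
``zeta = (zeta0, zeta1)`` the state-dependent relative rates constrained to
mean 1 ((zeta0 + zeta1)/2 = 1), and ``delta`` the reversible-jump indicator
(delta = 0 collapses to the state-independent model, zeta0 = zeta1 = 1).
Given a character history the trait covariance is that of plain BM on a tree
whose branch lengths are the *effective lengths*

    v_l = sigma2_global * beta_l * (t0_l * zeta0**delta + t1_l * zeta1**delta),

where t0, t1 are the dwell times of the history on branch l.

The likelihood is REML: the root state is marginalized and the density is the
product of the n-1 phylogenetically independent contrasts, each a k-variate
normal with covariance ``Sigma * V_c``.  ``Sigma`` (unit-diagonal, positive
definite) carries trait correlations and is a fixed model input.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np

from . import _kernels
from .discrete_history import CTMCRates, CharacterHistory, history_log_density
from .io_formats import PhyloTree, TraitMatrix

__all__ = [
    "ModelState",
    "effective_branch_length",
    "effective_branch_lengths",
    "pruning_loglik",
    "joint_log_posterior",
]


@dataclasses.dataclass
class ModelState:
    """One joint parameter configuration of the state-dependent rate model.

    ``beta`` is indexed by child node id (length n_nodes; entry 0 unused).
    """

    sigma2_global: float
    nu: float
    beta: np.ndarray
    zeta: tuple[float, float]
    delta: int
    rates: CTMCRates
    Sigma: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.Sigma = np.atleast_2d(np.asarray(self.Sigma, dtype=np.float64))
        self.validate()

    def validate(self) -> None:
        if not (self.sigma2_global > 0):
            raise ValueError("sigma2_global must be > 0")
        if not (self.nu >= 0):
            raise ValueError("nu must be >= 0")
        if np.any(self.beta[1:] <= 0):
            raise ValueError("all background rates beta must be > 0")
        z0, z1 = self.zeta
        if self.delta not in (0, 1):
            raise ValueError("delta must be 0 or 1")
        if self.delta == 0:
            if not (z0 == 1.0 and z1 == 1.0):
                raise ValueError("zeta must be (1, 1) when delta = 0")
        else:
            if not (z0 > 0 and z1 > 0):
                raise ValueError("zeta components must be > 0")
            if abs((z0 + z1) / 2.0 - 1.0) > 1e-9:
                raise ValueError("zeta must satisfy the mean-1 constraint")
        S = self.Sigma
        if S.shape[0] != S.shape[1] or not np.allclose(S, S.T):
            raise ValueError("Sigma must be symmetric")
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("Sigma must have unit diagonal")
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc

    @property
    def k(self) -> int:
        return self.Sigma.shape[0]


def effective_branch_length(branch: int, model_state: ModelState,
                            history: CharacterHistory) -> float:
    """Effective length of one branch: sigma2 * beta_l * sum_s t_s * zeta_s**delta."""
    dt = history.dwell_times()
    t0, t1 = dt[branch]
    if t0 < 0 or t1 < 0:
        raise ValueError("negative dwell time")
    z0, z1 = model_state.zeta
    d = model_state.delta
    return float(model_state.sigma2_global * model_state.beta[branch]
                 * (t0 * z0 ** d + t1 * z1 ** d))


def effective_branch_lengths(model_state: ModelState, history: CharacterHistory) -> np.ndarray:
    """Vector of effective lengths, indexed by child node id (entry 0 = 0)."""
    dt = history.dwell_times()
    if np.any(dt < 0):
        raise ValueError("negative dwell time")
    z0, z1 = model_state.zeta
    d = model_state.delta
    v = model_state.sigma2_global * model_state.beta * (
        dt[:, 0] * z0 ** d + dt[:, 1] * z1 ** d)
    v[0] = 0.0
    return v


def _sigma_inv_logdet(Sigma: np.ndarray) -> tuple[np.ndarray, float]:
    Sigma = np.atleast_2d(np.asarray(Sigma, dtype=np.float64))
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise ValueError("Sigma must be positive definite")
    return np.linalg.inv(Sigma), float(logdet)


def pruning_loglik(tree: PhyloTree, traits: TraitMatrix | np.ndarray,
                   effective_lengths: np.ndarray, Sigma: np.ndarray) -> float:
    """REML log-likelihood of the traits via independent contrasts.

    ``effective_lengths`` is indexed by child node id.  Each of the n-1
    contrasts contributes a k-variate normal log-density with mean 0 and
    covariance ``Sigma * V_c``; the root state is marginalized.  Returns -inf
    (with a warning) when tip values vary across a zero-variance contrast.
    """
    if isinstance(traits, TraitMatrix):
        if traits.labels != tree.tip_labels:
            raise ValueError("traits are not aligned to the tree")
        tipvals = traits.values
    else:
        tipvals = np.atleast_2d(np.asarray(traits, dtype=np.float64))
        if tipvals.shape[0] == 1 and tree.n_tips > 1:
            tipvals = tipvals.T
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    v = np.asarray(effective_lengths, dtype=np.float64)
    if v.shape != (tree.n_nodes,):
        raise ValueError("effective_lengths must be indexed by node id")
    if np.any(v[1:] < 0):
        raise ValueError("effective lengths must be >= 0")
    Sinv, logdetS = _sigma_inv_logdet(Sigma)
    k = Sinv.shape[0]
    if tipvals.shape != (tree.n_tips, k):
        raise ValueError("trait values must be (n_tips, k)")
    n = tree.n_nodes
    x = np.zeros((n, k))
    x[tree.tip_indices] = tipvals
    xw = np.empty((n, k))
    uw = np.empty(n)
    contrib = np.empty(n)
    ll = _kernels.full_fold(tree.parent, tree.child_ptr, tree.child_list,
                            tree.is_tip, v, x, Sinv, logdetS, xw, uw, contrib)
    if ll == -np.inf:
        warnings.warn("zero-variance contrast with varying tip values: log-likelihood is -inf")
    return float(ll)


def joint_log_posterior(model_state: ModelState, history: CharacterHistory,
                        tree: PhyloTree, traits: TraitMatrix, priors,
                        root_prior="stationary") -> float:
    """Unnormalized log posterior: trait REML + CTMC history density + priors.

    ``priors`` must expose ``log_density(model_state)`` (see
    :class:`statedep.mcmc_engine.Priors`).  Invariant violations raise; a
    valid state never silently maps to -inf through this term.
    """
    model_state.validate()
    v = effective_branch_lengths(model_state, history)
    ll = pruning_loglik(tree, traits, v, model_state.Sigma)
    lh = history_log_density(history, model_state.rates, root_prior)
    lp = priors.log_density(model_state)
    return float(ll + lh + lp)
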