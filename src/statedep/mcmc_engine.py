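"""Reversible-jump MCMC over the state-dependent rate model.

One generation of the sampler is a fixed sweep: a full-history move (a fresh
stochastic-mapping draw proposed from the CTMC conditional and accepted with
the trait-likelihood ratio), multiplier scale moves on sigma2, nu, q01 and
q10, a per-branch beta sweep with incremental likelihood updates, a joint
sigma2/beta rescale that walks along the sigma2 x beta ridge, a zeta simplex
move (active only under the state-dependent model) and the reversible-jump
toggle on delta.  The delta toggle proposes zeta from its prior (independence
sampler), so the Hastings ratio reduces to the likelihood ratio times the
prior odds of delta.

Move schedule and tuning constants are fixed, not adaptive, so a chain is a
deterministic function of its seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .io_formats import PhyloTree, RunConfig, TipStateTable, TraitMatrix, trace_columns
from .trait_likelihood import ModelState, _sigma_inv_logdet
from .discrete_history import CTMCRates

__all__ = [
    "Priors",
    "PosteriorTrace",
    "run_chain",
    "run_analysis",
    "rj_toggle",
    "diagnostics",
    "DiagnosticsReport",
]

# fixed proposal tuning: sigma2, nu, q, beta, joint rescale, zeta window
_TUNE = np.array([1.2, 1.2, 1.2, 0.8, 0.5, 0.2])


@dataclasses.dataclass
class Priors:
    """Hyperparameters of the joint prior.

    sigma2 ~ lognormal(sigma2_log_mean, sigma2_log_sd); nu ~ Exp(nu_rate)
    (default mean 0.587, about a two-fold expected spread of background
    rates); beta_l | nu ~ i.i.d. lognormal(0, nu) (median 1); (zeta0, zeta1)/2
    ~ Dirichlet(alpha, alpha) on the mean-1 simplex; P(delta = 1) = p_dep;
    q01, q10 ~ Exp(q_rate) (default mean 0.1 events per unit time).
    """

    sigma2_log_mean: float = 0.0
    sigma2_log_sd: float = 2.0
    nu_rate: float = 1.0 / 0.587
    zeta_alpha: float = 1.0
    p_dep: float = 0.5
    q_rate: float = 10.0

    def __post_init__(self):
        for name in ("sigma2_log_sd", "nu_rate", "zeta_alpha", "q_rate"):
            if not (getattr(self, name) > 0) or not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and positive")
        if not (0.0 < self.p_dep < 1.0):
            raise ValueError("p_dep must lie in (0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma2_log_mean, self.sigma2_log_sd, self.nu_rate,
                         self.zeta_alpha, self.p_dep, self.q_rate])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Priors":
        return cls(**d)

    # -- densities and sampling --------------------------------------------

    def log_density(self, state: ModelState) -> float:
        return float(_kernels.log_priors(
            state.sigma2_global, state.nu, state.rates.q01, state.rates.q10,
            state.zeta[0], state.delta, state.beta, self.as_array()))

    def sample_model_state(self, rng: np.random.Generator, n_nodes: int,
                           k: int = 1, Sigma: Optional[np.ndarray] = None,
                           fix_delta: Optional[int] = None) -> ModelState:
        sigma2 = float(np.exp(rng.normal(self.sigma2_log_mean, self.sigma2_log_sd)))
        nu = float(rng.exponential(1.0 / self.nu_rate))
        beta = np.ones(n_nodes)
        beta[1:] = np.exp(rng.normal(0.0, nu, n_nodes - 1))
        delta = int(rng.random() < self.p_dep) if fix_delta is None else int(fix_delta)
        if delta == 1:
            w0 = float(rng.beta(self.zeta_alpha, self.zeta_alpha))
            zeta = (2.0 * w0, 2.0 - 2.0 * w0)
        else:
            zeta = (1.0, 1.0)
        rates = CTMCRates(float(rng.exponential(1.0 / self.q_rate)),
                          float(rng.exponential(1.0 / self.q_rate)))
        if Sigma is None:
            Sigma = np.eye(k)
        return ModelState(sigma2_global=sigma2, nu=nu, beta=beta, zeta=zeta,
                          delta=delta, rates=rates, Sigma=Sigma)


@dataclasses.dataclass
class PosteriorTrace:
    """Retained posterior samples plus per-sample history summaries.

    ``df`` columns follow :func:`statedep.io_formats.trace_columns`; metadata
    records at least the seed, config hash and chain id.
    """

    df: pd.DataFrame
    branch_ids: list[str]
    metadata: dict

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def beta_matrix(self) -> np.ndarray:
        return self.df[[f"beta_{b}" for b in self.branch_ids]].to_numpy()

    def dwell1_matrix(self) -> np.ndarray:
        return self.df[[f"dwell1_{b}" for b in self.branch_ids]].to_numpy()

    @property
    def p_dep(self) -> float:
        return float(self.metadata.get("p_dep", 0.5))

    @classmethod
    def combine(cls, traces: Sequence["PosteriorTrace"]) -> "PosteriorTrace":
        if not traces:
            raise ValueError("no traces to combine")
        ids = traces[0].branch_ids
        for t in traces[1:]:
            if t.branch_ids != ids:
                raise ValueError("traces come from different trees")
        df = pd.concat([t.df for t in traces], ignore_index=True)
        meta = dict(traces[0].metadata)
        meta["chain_id"] = "combined"
        meta["n_chains"] = str(len(traces))
        return cls(df=df, branch_ids=ids, metadata=meta)


def _prepare_data(tree: PhyloTree, states: Optional[TipStateTable],
                  traits: Optional[TraitMatrix], Sigma, config: RunConfig):
    n = tree.n_nodes
    if states is not None:
        if states.labels != tree.tip_labels:
            raise ValueError("tip states not aligned to the tree")
        full_state = np.full(n, -1, dtype=np.int8)
        full_state[tree.tip_indices] = states.states
    else:
        full_state = np.zeros(n, dtype=np.int8)
    if traits is not None:
        if traits.labels != tree.tip_labels:
            raise ValueError("traits not aligned to the tree")
        k = traits.k
        vals = traits.values
        if config.log10_transform:
            vals = np.log10(vals)
        x = np.zeros((n, k))
        x[tree.tip_indices] = vals
    else:
        k = 1
        x = np.zeros((n, 1))
    if Sigma is None:
        Sigma = np.eye(k)
    Sinv, logdetS = _sigma_inv_logdet(Sigma)
    return full_state, x, np.asarray(Sigma, dtype=float), Sinv, logdetS, k


def run_chain(tree: PhyloTree, states: Optional[TipStateTable],
              traits: Optional[TraitMatrix], priors: Priors, run_config: RunConfig,
              chain_id: int = 0, Sigma: Optional[np.ndarray] = None) -> PosteriorTrace:
    """Run one chain and return the retained samples.

    With ``run_config.likelihood_on = False`` the trait likelihood is held at
    a constant and character histories are simulated unconditionally, so every
    parameter's marginal posterior equals its prior (the rj correctness gate).
    Initialization draws from the prior, re-drawing (up to 100 times) while
    the joint posterior is non-finite.
    """
    full_state, x, Sigma, Sinv, logdetS, k = _prepare_data(tree, states, traits, Sigma, run_config)
    if run_config.require_ultrametric:
        depths = tree.node_depths()[tree.tip_indices]
        if np.ptp(depths) > 1e-6 * max(depths.max(), 1.0):
            raise ValueError("tree is not ultrametric")
    n = tree.n_nodes
    thin = run_config.resolved_thinning()
    n_out = run_config.n_retained()
    post = int(run_config.n_generations * (1.0 - run_config.burnin_fraction))
    burnin_gen = run_config.n_generations - post
    if n_out < 1:
        raise ValueError("run configuration retains no samples")

    from .discrete_history import _root_mode

    root_mode, root_p0 = _root_mode(run_config.root_prior)
    ss = np.random.SeedSequence(entropy=run_config.rng_seed, spawn_key=(chain_id,))
    init_seed, kernel_seed = [int(s) % (2 ** 31 - 1) for s in ss.generate_state(2)]
    rng = np.random.default_rng(init_seed)

    likelihood_on = 1 if run_config.likelihood_on else 0
    conditional = 1 if run_config.likelihood_on else 0
    fix_delta = -1 if run_config.fix_delta is None else int(run_config.fix_delta)

    out = np.empty((n_out, 12 + 2 * (n - 1)))
    pr = priors.as_array()

    last_err = None
    for _ in range(100):
        ms = priors.sample_model_state(rng, n, k=k, Sigma=Sigma,
                                       fix_delta=run_config.fix_delta)
        init = np.array([ms.sigma2_global, ms.nu, ms.rates.q01, ms.rates.q10,
                         ms.zeta[0], ms.zeta[1], float(ms.delta)])
        beta = ms.beta.copy()
        _kernels.set_seed(kernel_seed)
        code = _kernels.run_chain_kernel(
            tree.parent, tree.blen, tree.child_ptr, tree.child_list, tree.is_tip,
            full_state, x, Sinv, logdetS, pr, _TUNE,
            run_config.n_generations, burnin_gen, thin,
            likelihood_on, conditional, root_mode, root_p0,
            1 if run_config.fix_q else 0, fix_delta,
            init, beta, out)
        if code == 0:
            break
        if code == 1:
            raise ValueError("tip configuration unreachable under the sampled CTMC rates")
        last_err = code
    else:
        raise RuntimeError(f"could not initialize a finite posterior state (code {last_err})")

    branch_ids = tree.branch_ids
    cols = trace_columns(branch_ids)
    nb = n - 1
    # kernel layout -> spec column order (beta block before gain/loss counts)
    data = {
        "generation": out[:, 0].astype(int),
        "log_posterior": out[:, 1],
        "log_likelihood": out[:, 2],
        "sigma2": out[:, 3],
        "nu": out[:, 4],
        "zeta0": out[:, 5],
        "zeta1": out[:, 6],
        "delta": out[:, 7].astype(int),
        "q01": out[:, 8],
        "q10": out[:, 9],
    }
    for i, b in enumerate(branch_ids):
        data[f"beta_{b}"] = out[:, 12 + i]
    data["n_gains"] = out[:, 10].astype(int)
    data["n_losses"] = out[:, 11].astype(int)
    for i, b in enumerate(branch_ids):
        data[f"dwell1_{b}"] = out[:, 12 + nb + i]
    df = pd.DataFrame(data)[cols]
    metadata = {
        "seed": str(run_config.rng_seed),
        "chain_id": str(chain_id),
        "config_hash": run_config.config_hash(),
        "p_dep": repr(priors.p_dep),
        "n_generations": str(run_config.n_generations),
        "thinning": str(thin),
        "burnin_fraction": repr(run_config.burnin_fraction),
    }
    return PosteriorTrace(df=df, branch_ids=branch_ids, metadata=metadata)


def run_analysis(tree: PhyloTree, states: Optional[TipStateTable],
                 traits: Optional[TraitMatrix], priors: Priors,
                 run_config: RunConfig, Sigma: Optional[np.ndarray] = None):
    """Run ``run_config.n_chains`` chains, check convergence, combine.

    Returns ``(combined, per_chain, report)``: chains are run with distinct
    seed streams, the between-chain PSRF is checked on the scalar parameters,
    then the post-burn-in samples are concatenated.
    """
    chains = [run_chain(tree, states, traits, priors, run_config, chain_id=c, Sigma=Sigma)
              for c in range(run_config.n_chains)]
    report = diagnostics(chains)
    combined = PosteriorTrace.combine(chains) if len(chains) > 1 else chains[0]
    return combined, chains, report


# ---------------------------------------------------------------------------
# Reversible-jump toggle (library-level, mirrors the kernel move)
# ---------------------------------------------------------------------------


def rj_toggle(state: ModelState, priors: Priors, rng: np.random.Generator):
    """Propose flipping the model indicator delta; returns (proposal, log_hastings).

    delta 0 -> 1 draws (zeta0, zeta1) from its prior; 1 -> 0 sets zeta = (1, 1).
    ``log_hastings`` is log q(old|new) - log q(new|old): for the prior
    independence sampler this is minus (resp. plus) the zeta prior log-density,
    so adding it to the full posterior ratio cancels the zeta prior exactly and
    acceptance reduces to the likelihood ratio times the prior odds of delta.
    """
    a = priors.zeta_alpha
    lbeta_const = math.lgamma(2 * a) - 2 * math.lgamma(a)
    if state.delta == 0:
        w0 = float(rng.beta(a, a))
        zeta = (2.0 * w0, 2.0 - 2.0 * w0)
        log_q = lbeta_const + (a - 1.0) * (math.log(w0) + math.log1p(-w0))
        proposal = dataclasses.replace(state, delta=1, zeta=zeta)
        return proposal, -log_q
    w0 = state.zeta[0] / 2.0
    log_q = lbeta_const + (a - 1.0) * (math.log(w0) + math.log1p(-w0))
    proposal = dataclasses.replace(state, delta=0, zeta=(1.0, 1.0))
    return proposal, log_q


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------

_SCALAR_PARAMS = ["log_posterior", "sigma2", "nu", "zeta0", "q01", "q10"]


@dataclasses.dataclass
class DiagnosticsReport:
    ess: dict
    psrf: Optional[dict]
    flagged: list

    def render(self) -> str:
        lines = ["parameter\tESS\tPSRF"]
        for p in self.ess:
            e = self.ess[p]
            r = self.psrf.get(p) if self.psrf else None
            lines.append(f"{p}\t{'undefined' if e != e else f'{e:.1f}'}\t"
                         f"{'-' if r is None or r != r else f'{r:.4f}'}")
        if self.flagged:
            lines.append("low ESS (< 200): " + ", ".join(self.flagged))
        return "\n".join(lines)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of one scalar chain (arviz, mean method); nan when constant."""
    x = np.asarray(x, dtype=float)
    if x.size < 4 or np.var(x) == 0:
        return float("nan")
    import arviz as az

    return float(az.ess(az.convert_to_dataset(x[None, :]), method="mean")["x"])


def potential_scale_reduction(chains: Sequence[np.ndarray]) -> float:
    """Classic Gelman-Rubin PSRF across >= 2 chains of equal length."""
    arr = np.asarray(chains, dtype=float)
    m, n = arr.shape
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    if W == 0:
        return float("nan")
    B = n * means.var(ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def diagnostics(traces: Sequence[PosteriorTrace],
                params: Optional[Sequence[str]] = None) -> DiagnosticsReport:
    """Per-parameter ESS (summed over chains) and between-chain PSRF.

    Constant columns report ESS as nan ("undefined"), never an error;
    parameters with total ESS < 200 are flagged.
    """
    if not traces:
        raise ValueError("need at least one trace")
    params = list(params) if params is not None else [
        p for p in _SCALAR_PARAMS if p in traces[0].df.columns]
    ess = {}
    flagged = []
    for p in params:
        vals = [effective_sample_size(t.df[p].to_numpy()) for t in traces]
        total = float(np.nansum(vals)) if not all(v != v for v in vals) else float("nan")
        ess[p] = total
        if total == total and total < 200:
            flagged.append(p)
    psrf = None
    if len(traces) >= 2:
        n = min(t.n_samples for t in traces)
        psrf = {p: potential_scale_reduction([t.df[p].to_numpy()[:n] for t in traces])
                for p in params}
    return DiagnosticsReport(ess=ess, psrf=psrf, flagged=flagged)
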