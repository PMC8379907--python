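"""Posterior summaries: hypothesis tests, rate partition, branch-rate maps.

Three hypotheses about the state-dependent rate multiplier zeta:

* H0 -- the state-independent model (delta = 0): zeta[builder] = zeta[nonbuilder];
* H1 -- state-dependent with zeta[builder] > zeta[nonbuilder];
* H2 -- state-dependent with zeta[builder] < zeta[nonbuilder].

Posterior probabilities are sample frequencies over the reversible-jump trace;
with a symmetric zeta prior the prior probabilities are (1 - p_dep, p_dep/2,
p_dep/2).  The Bayes factor of a hypothesis is its posterior odds divided by
its prior odds.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .io_formats import PhyloTree, TipStateTable, _fmt
from .mcmc_engine import PosteriorTrace

__all__ = [
    "HypothesisResult",
    "BranchRateSummary",
    "hypothesis_posteriors",
    "rate_variation_partition",
    "branch_rate_map",
]


@dataclasses.dataclass
class HypothesisResult:
    posterior: dict  # {"H0": p, "H1": p, "H2": p}
    prior: dict
    bayes_factors: dict  # {"H0": bf, "H1": bf, "H2": bf, "H1+H2": bf}
    mc_se: dict
    notes: dict

    def to_yaml(self, path: Optional[str] = None) -> str:
        payload = {
            "posterior": {k: float(v) for k, v in self.posterior.items()},
            "prior": {k: float(v) for k, v in self.prior.items()},
            "bayes_factors": {k: ("inf" if np.isinf(v) else float(v))
                              for k, v in self.bayes_factors.items()},
            "mc_se": {k: float(v) for k, v in self.mc_se.items()},
            "notes": dict(self.notes),
        }
        text = yaml.safe_dump(payload, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _bayes_factor(post_p: float, prior_p: float) -> float:
    """BF = [post/(1-post)] / [prior/(1-prior)], with honest infinities."""
    if prior_p <= 0.0:
        return float("nan")
    if post_p >= 1.0:
        return float("inf")
    post_odds = post_p / (1.0 - post_p)
    prior_odds = prior_p / (1.0 - prior_p)
    return post_odds / prior_odds


def _batch_se(indicator: np.ndarray, n_batches: int = 30) -> float:
    n = indicator.size
    if n < 2 * n_batches:
        n_batches = max(2, n // 2)
    usable = (n // n_batches) * n_batches
    means = indicator[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def hypothesis_posteriors(trace: PosteriorTrace, p_dep: Optional[float] = None) -> HypothesisResult:
    """Posterior probabilities, Bayes factors and MC errors for H0/H1/H2.

    H1/H2 are defined on delta = 1 samples only; numerically exact ties
    zeta1 = zeta0 under delta = 1 count to neither hypothesis.  A hypothesis
    with zero opposing samples reports BF = inf annotated with the
    rule-of-three finite-sample lower bound.
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if p_dep is None:
        p_dep = trace.p_dep
    df = trace.df
    delta = df["delta"].to_numpy().astype(int)
    z0 = df["zeta0"].to_numpy()
    z1 = df["zeta1"].to_numpy()
    n = delta.size
    ind = {
        "H0": (delta == 0),
        "H1": (delta == 1) & (z1 > z0),
        "H2": (delta == 1) & (z1 < z0),
    }
    post = {h: float(ind[h].mean()) for h in ind}
    prior = {"H0": 1.0 - p_dep, "H1": p_dep / 2.0, "H2": p_dep / 2.0}
    mc_se = {h: _batch_se(ind[h].astype(float)) for h in ind}
    bf = {h: _bayes_factor(post[h], prior[h]) for h in ind}
    dep = ind["H1"] | ind["H2"]
    post_dep = float(dep.mean())
    bf["H1+H2"] = _bayes_factor(post_dep, p_dep)
    mc_se["H1+H2"] = _batch_se(dep.astype(float))
    notes = {}
    for h, v in bf.items():
        if np.isinf(v):
            # rule of three: P(counter-hypothesis) <= 3/n at ~95% confidence
            pri = p_dep if h == "H1+H2" else prior[h]
            if n > 3:
                lower = ((1.0 - 3.0 / n) / (3.0 / n)) / (pri / (1.0 - pri))
                notes[h] = f"inf (no opposing samples; 95% lower bound {lower:.3g})"
            else:
                notes[h] = "inf (no opposing samples)"
    return HypothesisResult(posterior=post, prior=prior, bayes_factors=bf,
                            mc_se=mc_se, notes=notes)


def rate_variation_partition(trace: PosteriorTrace, tree: PhyloTree,
                             duration_weighted: bool = True,
                             log_scale: bool = True) -> tuple[float, str]:
    """Posterior-mean fraction of branch-rate variation due to the state effect.

    Per sample, each branch's log total relative rate decomposes into a
    state term log[(t0 zeta0**delta + t1 zeta1**delta)/t] and a background
    term log beta_l; the per-sample fraction is the (branch-duration-weighted)
    variance of the state term over the variance of their sum.  Returns
    (posterior mean fraction, note string recording the definition used).
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    beta = trace.beta_matrix()
    dwell1 = trace.dwell1_matrix()
    delta = trace.df["delta"].to_numpy()[:, None]
    z0 = trace.df["zeta0"].to_numpy()[:, None]
    z1 = trace.df["zeta1"].to_numpy()[:, None]
    state_mult = np.where(delta == 1, (1.0 - dwell1) * z0 + dwell1 * z1, 1.0)
    if log_scale:
        state_term = np.log(state_mult)
        back_term = np.log(beta)
    else:
        state_term = state_mult
        back_term = beta
    w = tree.blen[1:].astype(float)
    if not duration_weighted:
        w = np.ones_like(w)
    w = w / w.sum()

    def wvar(a):
        mu = a @ w
        return ((a - mu[:, None]) ** 2) @ w

    vs = wvar(state_term)
    vt = wvar(state_term + back_term)
    frac = np.where(vt > 0, vs / np.where(vt > 0, vt, 1.0), 0.0)
    note = ("definition=variance of per-branch {} rates, {}weighted by branch duration; "
            "zero total variance contributes 0").format(
                "log" if log_scale else "natural-scale",
                "" if duration_weighted else "un")
    return float(frac.mean()), note


@dataclasses.dataclass
class BranchRateSummary:
    """Posterior-mean per-branch rates, aligned to the tree's branch order."""

    branch_ids: list[str]
    total_rate: np.ndarray       # beta * state multiplier, posterior mean
    background_rate: np.ndarray  # posterior mean beta
    state_multiplier: np.ndarray  # posterior mean (t0 z0^d + t1 z1^d)/t
    builder_fraction: np.ndarray  # posterior mean dwell fraction in state 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "branch": self.branch_ids,
            "total_rate": self.total_rate,
            "background_rate": self.background_rate,
            "state_multiplier": self.state_multiplier,
            "builder_fraction": self.builder_fraction,
        })


def _annotated_newick(tree: PhyloTree, rates: np.ndarray) -> str:
    def visit(node: int) -> str:
        kids = tree.children(node)
        if kids.size == 0:
            s = tree._quote(tree.labels[node])
        else:
            s = "(" + ",".join(visit(int(c)) for c in kids) + ")"
            if tree.labels[node]:
                s += tree._quote(tree.labels[node])
        if node != 0:
            s += f"[&rate={_fmt(rates[node - 1])}]:{_fmt(tree.blen[node])}"
        return s

    return visit(0) + ";"


def _plot_rates(tree: PhyloTree, rates: np.ndarray, states: Optional[TipStateTable], path: str):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    depths = tree.node_depths()
    ys = np.zeros(tree.n_nodes)
    next_y = [0.0]

    def layout(node: int) -> float:
        kids = tree.children(node)
        if kids.size == 0:
            ys[node] = next_y[0]
            next_y[0] += 1.0
        else:
            ys[node] = np.mean([layout(int(c)) for c in kids])
        return ys[node]

    layout(0)
    segs, vals = [], []
    for node in range(1, tree.n_nodes):
        p = tree.parent[node]
        segs.append([(depths[p], ys[node]), (depths[node], ys[node])])
        segs.append([(depths[p], ys[p]), (depths[p], ys[node])])
        vals.extend([rates[node - 1]] * 2)
    fig, ax = plt.subplots(figsize=(7, max(3, tree.n_tips * 0.12)))
    lc = LineCollection(segs, cmap="viridis", array=np.log10(np.asarray(vals)))
    ax.add_collection(lc)
    fig.colorbar(lc, ax=ax, label="log10 posterior-mean relative rate")
    if states is not None:
        lookup = dict(zip(states.labels, states.states))
        for i in tree.tip_indices:
            col = "red" if lookup[tree.labels[i]] == 1 else "lightblue"
            ax.plot(depths[i], ys[i], "o", ms=4, color=col, zorder=3)
    ax.set_xlim(-0.02 * depths.max(), 1.05 * depths.max())
    ax.set_ylim(-1, tree.n_tips)
    ax.set_yticks([])
    ax.set_xlabel("time")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def branch_rate_map(trace: PosteriorTrace, tree: PhyloTree,
                    states: Optional[TipStateTable] = None,
                    out_prefix: Optional[str] = None) -> BranchRateSummary:
    """Posterior-mean per-branch rate summaries; optionally write map outputs.

    With ``out_prefix`` writes ``<prefix>branch_rates.tsv``, ``<prefix>rates.nwk``
    (newick with ``[&rate=...]`` comments) and ``<prefix>rates.svg`` (tips
    colored by state: red = builder, light blue = nonbuilder).
    """
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    if trace.branch_ids != tree.branch_ids:
        raise ValueError("trace branches do not match the tree")
    beta = trace.beta_matrix()
    dwell1 = trace.dwell1_matrix()
    delta = trace.df["delta"].to_numpy()[:, None]
    z0 = trace.df["zeta0"].to_numpy()[:, None]
    z1 = trace.df["zeta1"].to_numpy()[:, None]
    mult = np.where(delta == 1, (1.0 - dwell1) * z0 + dwell1 * z1, 1.0)
    summary = BranchRateSummary(
        branch_ids=list(trace.branch_ids),
        total_rate=(beta * mult).mean(axis=0),
        background_rate=beta.mean(axis=0),
        state_multiplier=mult.mean(axis=0),
        builder_fraction=dwell1.mean(axis=0),
    )
    if out_prefix is not None:
        df = summary.to_frame()
        with open(out_prefix + "branch_rates.tsv", "w") as fh:
            fh.write("\t".join(df.columns) + "\n")
            for _, row in df.iterrows():
                cells = [row.iloc[0]] + [_fmt(v) for v in row.iloc[1:]]
                fh.write("\t".join(cells) + "\n")
        with open(out_prefix + "rates.nwk", "w") as fh:
            fh.write(_annotated_newick(tree, summary.total_rate) + "\n")
        _plot_rates(tree, summary.total_rate, states, out_prefix + "rates.svg")
    return summary
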