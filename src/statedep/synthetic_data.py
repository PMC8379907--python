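"""Synthetic data under the exact generative model the inference assumes.

The generator is the study's stand-in for real comparative data: a Yule
(pure-birth) time tree, a two-state lifestyle character simulated forward
along it, branch-specific background rates drawn i.i.d. lognormal(0, nu)
(median 1), and continuous traits diffusing with the state-dependent
Brownian-motion variance.  A truth manifest records every parameter so that
recovery tests can score the inference against the generating values.

Default regime (the study conditions for recovery tests): 200 tips, one
trait, zeta = (0.25, 1.75) under the state-dependent truth (rate ratio 7),
nu = 0.3, and symmetric CTMC rates calibrated so the expected number of
lifestyle transitions on the realized tree is about 20 -- a strong but
realistic effect comparable to the few-dozen gains/losses seen on real
spider trees.

Randomness is stream-split: tree, character history, background rates and
traits each consume an independent child of the dataset's seed sequence, so
e.g. changing the number of traits never perturbs the tree.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Optional

import numpy as np
import yaml

from .discrete_history import CTMCRates, CharacterHistory
from .io_formats import (PhyloTree, TipStateTable, TraitMatrix, write_newick,
                         write_states, write_traits, _fmt)
from .trait_likelihood import ModelState

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_yule",
    "simulate_history",
    "simulate_traits",
    "generate_dataset",
    "rates_for_expected_transitions",
]


def simulate_yule(n_tips: int, birth_rate: float, seed) -> PhyloTree:
    """Pure-birth ultrametric tree with ``n_tips`` tips.

    Waiting times while k lineages exist are Exp(k * birth_rate); the present
    is the moment the (n_tips + 1)-th split would occur, so the expected root
    height is sum_{k=2}^{n} 1/(k * birth_rate).  Deterministic given seed.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth_rate > 0):
        raise ValueError("birth_rate must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # split j (of n-1) happens after an Exp(j * lambda) wait with j lineages;
    # the present is the moment split n would have happened
    t = 0.0
    split_times = []
    for j in range(1, n_tips):
        t += rng.exponential(1.0 / (j * birth_rate))
        split_times.append(t)
    present = t + rng.exponential(1.0 / (n_tips * birth_rate))

    parent: list[int] = []
    blen: list[float] = []
    children: list[list[int]] = []
    # active lineages: (birth_time, parent_node_id); the stem has parent -1
    active: list[tuple[float, int]] = [(0.0, -1)]
    for j, s in enumerate(split_times):
        pick = 0 if j == 0 else int(rng.integers(len(active)))
        birth, pa = active.pop(pick)
        idx = len(parent)
        parent.append(pa)
        blen.append(s - birth if pa >= 0 else 0.0)
        children.append([])
        if pa >= 0:
            children[pa].append(idx)
        active.append((s, idx))
        active.append((s, idx))
    for birth, pa in active:
        idx = len(parent)
        parent.append(pa)
        blen.append(present - birth)
        children.append([])
        children[pa].append(idx)
    # reorder to preorder
    order = []
    stack = [0]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(reversed(children[node]))
    rank = {old: new for new, old in enumerate(order)}
    new_parent = np.array([-1] + [rank[parent[o]] for o in order[1:]], dtype=np.int64)
    new_blen = np.array([0.0] + [blen[o] for o in order[1:]])
    labels: list[Optional[str]] = []
    tip_counter = 0
    for o in order:
        if not children[o]:
            tip_counter += 1
            labels.append(f"t{tip_counter}")
        else:
            labels.append(None)
    return PhyloTree(new_parent, new_blen, labels)


def rates_for_expected_transitions(tree: PhyloTree, n_expected: float) -> CTMCRates:
    """Symmetric CTMC rates giving ~``n_expected`` flips on this tree.

    With q01 = q10 = q the character flips at rate q in both states, so the
    expected flip count is q times the total tree length.
    """
    total = tree.total_length()
    if total <= 0:
        raise ValueError("tree has zero total length")
    q = n_expected / total
    return CTMCRates(q, q)


def simulate_history(tree: PhyloTree, q01: float, q10: float,
                     root_state: Optional[int] = None, seed=None) -> CharacterHistory:
    """Forward-simulate a character history from the root down.

    ``root_state=None`` draws the root from the CTMC stationary distribution;
    both rates 0 with no root state is an error (the process is undefined).
    Deterministic given seed.
    """
    rates = CTMCRates(q01, q10)
    if q01 == 0 and q10 == 0 and root_state is None:
        raise ValueError("both rates 0: a root_state must be given")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = tree.n_nodes
    node_states = np.zeros(n, dtype=np.int8)
    if root_state is None:
        node_states[0] = 0 if rng.random() < rates.stationary_p0() else 1
    else:
        node_states[0] = int(root_state)
    seg_states: list[np.ndarray] = []
    seg_durs: list[np.ndarray] = []
    for node in range(1, n):
        cur = int(node_states[tree.parent[node]])
        t = float(tree.blen[node])
        sts, dus = [], []
        tt = 0.0
        while True:
            rate = q01 if cur == 0 else q10
            dt = rng.exponential(1.0 / rate) if rate > 0 else t - tt + 1.0
            if tt + dt >= t:
                sts.append(cur)
                dus.append(t - tt)
                break
            sts.append(cur)
            dus.append(dt)
            tt += dt
            cur = 1 - cur
        node_states[node] = cur
        seg_states.append(np.array(sts, dtype=np.int8))
        seg_durs.append(np.array(dus))
    return CharacterHistory(tree, node_states, seg_states, seg_durs)


def simulate_traits(tree: PhyloTree, history: CharacterHistory,
                    model_state: ModelState, seed=None,
                    root_value: float = 0.0,
                    trait_names: Optional[list[str]] = None,
                    validate: bool = True) -> TraitMatrix:
    """Diffuse traits down the tree under the state-dependent BM model.

    Each child value is Normal(parent, Sigma * v_eff) per trait dimension,
    with v_eff the effective branch length from the history and model state.
    The root value defaults to 0 on the log scale (the REML likelihood is
    translation-invariant, so this is a pure convention).
    """
    from .trait_likelihood import effective_branch_lengths

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = effective_branch_lengths(model_state, history)
    k = model_state.k
    L = np.linalg.cholesky(model_state.Sigma)
    n = tree.n_nodes
    x = np.zeros((n, k))
    x[0] = root_value
    for node in range(1, n):
        z = rng.standard_normal(k)
        x[node] = x[tree.parent[node]] + np.sqrt(v[node]) * (L @ z)
    names = trait_names or [f"trait{i + 1}" for i in range(k)]
    return TraitMatrix(labels=tree.tip_labels, trait_names=names,
                       values=x[tree.tip_indices], validate=validate)


@dataclasses.dataclass
class SimConfig:
    """Configuration of one synthetic dataset (the generative study conditions)."""

    n_tips: int = 200
    birth_rate: float = 1.0
    q01: Optional[float] = None
    q10: Optional[float] = None
    expected_transitions: float = 20.0
    root_state: Optional[int] = None
    sigma2: float = 1.0
    nu: float = 0.3
    zeta: tuple[float, float] = (0.25, 1.75)
    delta: int = 1
    k_traits: int = 1
    Sigma: Optional[np.ndarray] = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["zeta"] = list(self.zeta)
        if self.Sigma is not None:
            d["Sigma"] = np.asarray(self.Sigma).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "zeta" in d:
            d["zeta"] = tuple(d["zeta"])
        if d.get("Sigma") is not None:
            d["Sigma"] = np.asarray(d["Sigma"], dtype=float)
        return cls(**d)


@dataclasses.dataclass
class SyntheticDataset:
    tree: PhyloTree
    tip_states: TipStateTable
    traits: TraitMatrix
    true_history: CharacterHistory
    truth: ModelState
    seed: int
    config: SimConfig


def generate_dataset(sim_config: SimConfig, out_dir: Optional[str] = None) -> SyntheticDataset:
    """Generate tree, character history, background rates and traits.

    Re-running with the same config reproduces byte-identical files.  With
    ``out_dir`` writes tree.nwk, states.tsv, traits.tsv, history.tsv and
    truth.yaml (the truth manifest; flags a state-independent truth when the
    generating model has delta = 0 or equal zetas).
    """
    cfg = sim_config
    ss = np.random.SeedSequence(cfg.seed)
    tree_rng, hist_rng, beta_rng, trait_rng = [np.random.default_rng(s) for s in ss.spawn(4)]
    tree = simulate_yule(cfg.n_tips, cfg.birth_rate, tree_rng)
    if cfg.q01 is None or cfg.q10 is None:
        rates = rates_for_expected_transitions(tree, cfg.expected_transitions)
    else:
        rates = CTMCRates(cfg.q01, cfg.q10)
    history = simulate_history(tree, rates.q01, rates.q10, cfg.root_state, hist_rng)
    beta = np.ones(tree.n_nodes)
    beta[1:] = np.exp(beta_rng.normal(0.0, cfg.nu, tree.n_nodes - 1))
    zeta = tuple(cfg.zeta) if cfg.delta == 1 else (1.0, 1.0)
    Sigma = np.eye(cfg.k_traits) if cfg.Sigma is None else np.asarray(cfg.Sigma, float)
    truth = ModelState(sigma2_global=cfg.sigma2, nu=cfg.nu, beta=beta,
                       zeta=zeta, delta=cfg.delta, rates=rates, Sigma=Sigma)
    traits = simulate_traits(tree, history, truth, trait_rng, validate=False)
    dataset = SyntheticDataset(tree=tree, tip_states=history.tip_states(),
                               traits=traits, true_history=history, truth=truth,
                               seed=cfg.seed, config=cfg)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_newick(tree, os.path.join(out_dir, "tree.nwk"))
        write_states(dataset.tip_states, os.path.join(out_dir, "states.tsv"))
        write_traits(traits, os.path.join(out_dir, "traits.tsv"))
        hist_df = history.to_frame()
        with open(os.path.join(out_dir, "history.tsv"), "w") as fh:
            fh.write("\t".join(hist_df.columns) + "\n")
            for _, row in hist_df.iterrows():
                fh.write(f"{row['branch']}\t{row['segment']}\t{row['state']}\t"
                         f"{_fmt(row['duration'])}\n")
        ng, nl = history.count_transitions()
        manifest = {
            "config": cfg.to_dict(),
            "state_independent_truth": bool(cfg.delta == 0 or zeta[0] == zeta[1]),
            "sigma2": float(cfg.sigma2),
            "nu": float(cfg.nu),
            "zeta": [float(zeta[0]), float(zeta[1])],
            "delta": int(cfg.delta),
            "q01": float(rates.q01),
            "q10": float(rates.q10),
            "beta": [float(b) for b in beta[1:]],
            "n_gains": int(ng),
            "n_losses": int(nl),
            "seed": int(cfg.seed),
        }
        with open(os.path.join(out_dir, "truth.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return dataset
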