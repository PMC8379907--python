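"""Two-state continuous-time Markov chain machinery for the lifestyle character.

The discrete character (0 = nonbuilder, 1 = builder) evolves along the tree as
a two-state CTMC with gain rate ``q01`` and loss rate ``q10``.  The inference
never integrates the character out: instead full character histories --
piecewise-constant state functions on every branch -- are sampled conditional
on the tip states (stochastic mapping / data augmentation), which makes the
state-dependent trait likelihood an exact function of per-branch dwell times.

Conditional sampling is exact: internal node states are drawn by Felsenstein
pruning followed by recursive conditioning from the root down, and each branch
path is drawn by endpoint-conditioned uniformization with auxiliary-jump rate
1.1 x max(q01, q10).
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import _kernels
from .io_formats import PhyloTree, TipStateTable

__all__ = [
    "CTMCRates",
    "CharacterHistory",
    "transition_matrix",
    "sample_history",
    "count_transitions",
    "dwell_times",
    "history_log_density",
]


@dataclasses.dataclass
class CTMCRates:
    """Gain (0->1) and loss (1->0) rates, in events per unit branch time."""

    q01: float
    q10: float

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("CTMC rates must be >= 0")

    def stationary_p0(self) -> float:
        qs = self.q01 + self.q10
        return self.q10 / qs if qs > 0 else 0.5


def transition_matrix(rates: CTMCRates, t: float) -> np.ndarray:
    """Closed-form 2x2 transition-probability matrix exp(Q t)."""
    if t < 0:
        raise ValueError("elapsed time must be >= 0")
    p00, p01, p10, p11 = _kernels.pij(rates.q01, rates.q10, float(t))
    return np.array([[p00, p01], [p10, p11]])


class CharacterHistory:
    """A full realization of the binary character along every branch.

    Per branch (indexed by child node id) an ordered list of (state, duration)
    segments running from the parent end to the child end; adjacent segments
    alternate states and durations sum to the branch length.
    """

    def __init__(self, tree: PhyloTree, node_states: np.ndarray,
                 seg_states: list[np.ndarray], seg_durs: list[np.ndarray],
                 validate: bool = True):
        self.tree = tree
        self.node_states = np.asarray(node_states, dtype=np.int8)
        self.seg_states = seg_states  # seg_states[i] for branch above node i+1... see branch()
        self.seg_durs = seg_durs
        if validate:
            self.validate()

    def branch(self, node: int):
        """Segments (states, durations) of the branch above ``node``."""
        return self.seg_states[node - 1], self.seg_durs[node - 1]

    def validate(self, tol: float = 1e-9) -> None:
        tree = self.tree
        if self.node_states.shape != (tree.n_nodes,):
            raise ValueError("node_states must be one state per node")
        if len(self.seg_states) != tree.n_nodes - 1:
            raise ValueError("one segment list per branch required")
        for node in range(1, tree.n_nodes):
            st, du = self.branch(node)
            if st.shape != du.shape or st.size == 0:
                raise ValueError(f"branch {node}: malformed segments")
            if np.any(du < 0):
                raise ValueError(f"branch {node}: negative segment duration")
            if abs(du.sum() - tree.blen[node]) > tol:
                raise ValueError(f"branch {node}: segment durations do not sum to the branch length")
            if np.any(st[1:] == st[:-1]):
                raise ValueError(f"branch {node}: adjacent segments must alternate states")
            if st[0] != self.node_states[tree.parent[node]]:
                raise ValueError(f"branch {node}: start state != parent node state")
            if st[-1] != self.node_states[node]:
                raise ValueError(f"branch {node}: end state != child node state")

    def tip_states(self) -> TipStateTable:
        tree = self.tree
        return TipStateTable(labels=tree.tip_labels,
                             states=self.node_states[tree.tip_indices])

    def dwell_times(self) -> np.ndarray:
        """(n_nodes, 2) array of per-branch time in state 0 and state 1."""
        out = np.zeros((self.tree.n_nodes, 2))
        for node in range(1, self.tree.n_nodes):
            st, du = self.branch(node)
            out[node, 0] = du[st == 0].sum()
            out[node, 1] = du[st == 1].sum()
        return out

    def count_transitions(self) -> tuple[int, int]:
        """(n_gains, n_losses): number of 0->1 and 1->0 switch points."""
        ng = nl = 0
        for node in range(1, self.tree.n_nodes):
            st, _ = self.branch(node)
            ng += int(np.sum((st[:-1] == 0) & (st[1:] == 1)))
            nl += int(np.sum((st[:-1] == 1) & (st[1:] == 0)))
        return ng, nl

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in range(1, self.tree.n_nodes):
            st, du = self.branch(node)
            for i in range(st.size):
                rows.append((f"b{node}", i, int(st[i]), float(du[i])))
        return pd.DataFrame(rows, columns=["branch", "segment", "state", "duration"])


def count_transitions(history: CharacterHistory) -> tuple[int, int]:
    return history.count_transitions()


def dwell_times(history: CharacterHistory) -> np.ndarray:
    return history.dwell_times()


def _root_mode(root_prior: Union[str, int]) -> tuple[int, float]:
    if root_prior == "stationary":
        return 0, 0.5
    if root_prior in (0, 1):
        return 1, 1.0 if root_prior == 0 else 0.0
    if isinstance(root_prior, float) and 0.0 <= root_prior <= 1.0:
        return 1, root_prior
    raise ValueError("root_prior must be 'stationary', a state 0/1, or P(root=0)")


def _history_from_flat(tree: PhyloTree, node_state, seg_ptr, seg_state, seg_dur) -> CharacterHistory:
    seg_states = []
    seg_durs = []
    for node in range(1, tree.n_nodes):
        lo, hi = seg_ptr[node], seg_ptr[node + 1]
        seg_states.append(np.array(seg_state[lo:hi], dtype=np.int8))
        seg_durs.append(np.array(seg_dur[lo:hi], dtype=np.float64))
    return CharacterHistory(tree, node_state, seg_states, seg_durs, validate=False)


def sample_history(tree: PhyloTree, tip_states: TipStateTable, rates: CTMCRates,
                   root_prior: Union[str, int] = "stationary",
                   seed: Optional[int] = None) -> CharacterHistory:
    """Exact conditional draw of a character history given the tip states.

    Impossible tip configurations (e.g. a builder tip with q01 = 0 below an
    all-nonbuilder ancestry) are detected exactly by the pruning pass, which
    finds zero conditional mass, and raise ``ValueError`` immediately.
    """
    if tip_states.labels != tree.tip_labels:
        raise ValueError("tip states are not aligned to the tree")
    full_state = np.full(tree.n_nodes, -1, dtype=np.int8)
    full_state[tree.tip_indices] = tip_states.states
    mode, p0 = _root_mode(root_prior)
    if seed is not None:
        _kernels.set_seed(int(seed))
    n = tree.n_nodes
    node_state = np.zeros(n, dtype=np.int8)
    f0 = np.empty(n)
    f1 = np.empty(n)
    dwell0 = np.zeros(n)
    seg_ptr = np.zeros(n + 1, dtype=np.int64)
    cap = 8 * n + 64
    times_buf = np.empty(1024)
    err = 2
    while err == 2:
        seg_state = np.empty(cap, dtype=np.int8)
        seg_dur = np.empty(cap)
        err, _, _ = _kernels.sample_history_into(
            tree.parent, tree.blen, tree.is_tip, full_state,
            float(rates.q01), float(rates.q10), mode, p0, 1,
            node_state, f0, f1, dwell0, seg_ptr, seg_state, seg_dur, times_buf)
        cap *= 2
    if err != 0:
        raise ValueError("tip configuration unreachable under the given CTMC rates")
    return _history_from_flat(tree, node_state, seg_ptr, seg_state, seg_dur)


def history_log_density(history: CharacterHistory, rates: CTMCRates,
                        root_prior: Union[str, int] = "stationary") -> float:
    """Log density of a history under the CTMC with the given root prior."""
    dt = history.dwell_times()
    ng, nl = history.count_transitions()
    mode, p0 = _root_mode(root_prior)
    return float(_kernels.history_logdensity(
        ng, nl, dt[:, 0].sum(), dt[:, 1].sum(), int(history.node_states[0]),
        float(rates.q01), float(rates.q10), mode, p0))
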