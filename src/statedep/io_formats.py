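"""On-disk formats: newick trees, TSV tip tables, posterior traces, YAML config.

All readers validate strictly and raise :class:`FormatError` on any violation of
the container invariants; nothing is silently imputed or defaulted.  Floats are
printed with 17 significant digits so that every writer/reader pair round-trips
float64 values exactly.

Node indexing convention: nodes are stored in preorder (root first, children in
file order), so node 0 is the root and ``parent[i] < i`` for every non-root
node.  Branches are identified by their child node id; only tip labels are
user-facing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "PhyloTree",
    "TipStateTable",
    "TraitMatrix",
    "RunConfig",
    "read_newick",
    "write_newick",
    "read_tip_tables",
    "read_states",
    "read_traits",
    "write_states",
    "write_traits",
    "write_trace",
    "read_trace",
    "read_run_config",
    "write_run_config",
]

_FLOAT_FMT = "%.17g"


class FormatError(ValueError):
    """Raised when an on-disk artifact violates a format or type invariant."""


def _fmt(x: float) -> str:
    return _FLOAT_FMT % float(x)


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------


class PhyloTree:
    """Rooted (time-calibrated) phylogeny stored as flat preorder arrays.

    Parameters
    ----------
    parent
        int array, ``parent[0] == -1`` for the root, ``parent[i] < i`` otherwise.
    blen
        float array of branch lengths (length of the edge above each node);
        ``blen[0]`` is 0 for the root.  All lengths must be >= 0.
    labels
        per-node label; tips must carry unique non-empty labels, internal
        labels are optional (may be None).
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray, labels: Sequence[Optional[str]]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.shape[0]
        if self.blen.shape[0] != n or len(self.labels) != n:
            raise FormatError("parent, blen and labels must have equal length")
        self._build_derived()
        self.validate()

    def _build_derived(self) -> None:
        n = self.n_nodes
        counts = np.zeros(n, dtype=np.int64)
        for i in range(1, n):
            counts[self.parent[i]] += 1
        self.child_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(counts, out=self.child_ptr[1:])
        self.child_list = np.empty(n - 1 if n > 0 else 0, dtype=np.int64)
        fill = self.child_ptr[:-1].copy()
        for i in range(1, n):
            p = self.parent[i]
            self.child_list[fill[p]] = i
            fill[p] += 1
        self.is_tip = counts == 0
        self.tip_indices = np.flatnonzero(self.is_tip)

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n = self.n_nodes
        if n < 1:
            raise FormatError("empty tree")
        if self.parent[0] != -1:
            raise FormatError("node 0 must be the root (parent -1)")
        if n > 1 and not np.all(self.parent[1:] >= 0):
            raise FormatError("tree must have exactly one root")
        if n > 1 and not np.all(self.parent[1:] < np.arange(1, n)):
            raise FormatError("nodes must be stored in preorder (parent before child)")
        if np.any(self.blen < 0) or not np.all(np.isfinite(self.blen)):
            raise FormatError("all branch lengths must be finite and >= 0")
        tips = [self.labels[i] for i in self.tip_indices]
        if any(lbl is None or lbl == "" for lbl in tips):
            raise FormatError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dups = sorted({t for t in tips if tips.count(t) > 1})
            raise FormatError(f"duplicate tip labels: {dups}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def n_tips(self) -> int:
        return int(self.tip_indices.shape[0])

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in preorder (deterministic file order)."""
        return [self.labels[i] for i in self.tip_indices]

    @property
    def branch_nodes(self) -> np.ndarray:
        """Child-node ids of all branches, in preorder (1..n_nodes-1)."""
        return np.arange(1, self.n_nodes, dtype=np.int64)

    @property
    def branch_ids(self) -> list[str]:
        return [f"b{i}" for i in self.branch_nodes]

    def children(self, node: int) -> np.ndarray:
        return self.child_list[self.child_ptr[node] : self.child_ptr[node + 1]]

    def total_length(self) -> float:
        return float(self.blen[1:].sum())

    def node_depths(self) -> np.ndarray:
        """Time from the root to each node."""
        d = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            d[i] = d[self.parent[i]] + self.blen[i]
        return d

    # -- newick -------------------------------------------------------------

    @staticmethod
    def _quote(label: str) -> str:
        if any(c in label for c in "()[]{}/\\,;:=*'\"`+<> \t\n"):
            return "'" + label.replace("'", "''") + "'"
        return label

    def _newick_node(self, node: int, with_blen: bool = True) -> str:
        kids = self.children(node)
        if kids.size == 0:
            s = self._quote(self.labels[node])
        else:
            s = "(" + ",".join(self._newick_node(int(c), with_blen) for c in kids) + ")"
            if self.labels[node]:
                s += self._quote(self.labels[node])
        if with_blen and node != 0:
            s += ":" + _fmt(self.blen[node])
        return s

    def to_newick(self) -> str:
        return self._newick_node(0) + ";"

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        root = dtree.seed_node
        parent: list[int] = []
        blen: list[float] = []
        labels: list[Optional[str]] = []
        index: dict = {}

        def visit(node, parent_idx: int) -> None:
            idx = len(parent)
            index[node] = idx
            parent.append(parent_idx)
            if parent_idx == -1:
                blen.append(0.0)
            else:
                if node.edge.length is None:
                    raise FormatError("missing branch length on a non-root edge")
                blen.append(float(node.edge.length))
            lbl = None
            if node.taxon is not None and node.taxon.label is not None:
                lbl = str(node.taxon.label)
            elif node.label is not None:
                lbl = str(node.label)
            labels.append(lbl)
            for child in node.child_nodes():
                visit(child, idx)

        visit(root, -1)
        return cls(np.array(parent), np.array(blen), labels)

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises a zoo of parse errors
            raise FormatError(f"could not parse newick: {exc}") from exc
        return cls.from_dendropy(dtree)


def read_newick(path: str) -> PhyloTree:
    """Read a rooted tree with mandatory branch lengths from a newick file.

    Quoted labels are allowed and ``[...]`` comments are stripped (dendropy
    semantics).  Duplicate tip labels or a missing branch length on any
    non-root edge are format errors; nothing is silently defaulted.
    """
    with open(path) as fh:
        text = fh.read()
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Tip tables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TipStateTable:
    """Binary lifestyle state per tip: 0 = nonbuilder, 1 = builder.

    ``labels`` follow the tree's preorder tip ordering exactly.
    """

    labels: list[str]
    states: np.ndarray  # int8, values in {0, 1}

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.labels),):
            raise FormatError("states must be one value per tip label")
        bad = ~np.isin(self.states, (0, 1))
        if bad.any():
            raise FormatError("state must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tip": self.labels, "state": self.states.astype(int)})


@dataclasses.dataclass
class TraitMatrix:
    """Continuous (log-scale) trait values, tips x traits, aligned to the tree.

    Rows follow the tree's preorder tip ordering; no missing cells are allowed
    and (on read) every trait must vary across tips.
    """

    labels: list[str]
    trait_names: list[str]
    values: np.ndarray  # float64 (n_tips, k)
    validate: dataclasses.InitVar[bool] = True

    def __post_init__(self, validate: bool = True):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.labels), len(self.trait_names)):
            raise FormatError("trait values must be (n_tips, n_traits)")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("missing or non-finite trait values are not supported")
        if validate and len(self.labels) > 1:
            var = self.values.var(axis=0)
            flat = [self.trait_names[j] for j in np.flatnonzero(var == 0)]
            if flat:
                raise FormatError(f"traits with zero variance across tips: {flat}")

    @property
    def k(self) -> int:
        return len(self.trait_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.trait_names)
        df.insert(0, "tip", self.labels)
        return df


def _read_tip_frame(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a tip-label column plus data columns")
    return df


def _align(df: pd.DataFrame, tree: PhyloTree, path: str) -> pd.DataFrame:
    tipcol = df.columns[0]
    labels = df[tipcol].tolist()
    if len(set(labels)) != len(labels):
        raise FormatError(f"{path}: duplicate tip rows")
    tree_tips = tree.tip_labels
    missing = sorted(set(tree_tips) - set(labels))
    if missing:
        raise FormatError(f"{path}: tips in tree absent from table: {missing}")
    orphans = sorted(set(labels) - set(tree_tips))
    if orphans:
        raise FormatError(f"{path}: table rows not in tree: {orphans}")
    return df.set_index(tipcol).loc[tree_tips].reset_index()


def read_states(path: str, tree: PhyloTree) -> TipStateTable:
    df = _align(_read_tip_frame(path), tree, path)
    col = df.columns[1]
    vals = df[col].to_numpy()
    arr = np.asarray(vals)
    if not np.all(np.isin(arr, (0, 1))):
        raise FormatError(f"{path}: state must be 0 or 1")
    return TipStateTable(labels=df[df.columns[0]].tolist(), states=arr.astype(np.int8))


def read_traits(path: str, tree: PhyloTree) -> TraitMatrix:
    df = _align(_read_tip_frame(path), tree, path)
    names = list(df.columns[1:])
    vals = df[names].to_numpy(dtype=float)
    return TraitMatrix(labels=df[df.columns[0]].tolist(), trait_names=names, values=vals)


def read_tip_tables(states_path: str, traits_path: str, tree: PhyloTree):
    """Read and tree-align the binary-state and trait tables (TSV, header row)."""
    return read_states(states_path, tree), read_traits(traits_path, tree)


def _write_tip_frame(df: pd.DataFrame, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            cells = [
                _fmt(v) if isinstance(v, float) else str(v)
                for v in row.tolist()
            ]
            fh.write("\t".join(cells) + "\n")


def write_states(table: TipStateTable, path: str) -> None:
    _write_tip_frame(table.to_frame(), path)


def write_traits(traits: TraitMatrix, path: str) -> None:
    _write_tip_frame(traits.to_frame(), path)


# ---------------------------------------------------------------------------
# Posterior traces
# ---------------------------------------------------------------------------

TRACE_MAGIC = "# statedep-trace v1"


def trace_columns(branch_ids: Sequence[str]) -> list[str]:
    cols = [
        "generation",
        "log_posterior",
        "log_likelihood",
        "sigma2",
        "nu",
        "zeta0",
        "zeta1",
        "delta",
        "q01",
        "q10",
    ]
    cols += [f"beta_{b}" for b in branch_ids]
    cols += ["n_gains", "n_losses"]
    cols += [f"dwell1_{b}" for b in branch_ids]
    return cols


def write_trace(trace, path: str) -> None:
    """Write a posterior trace as TSV with a commented metadata header.

    One row per retained sample; floats at 17 significant digits so that
    ``read_trace`` is the exact inverse.  Raises on an empty trace.
    """
    if trace.n_samples == 0:
        raise FormatError("refusing to write an empty trace")
    cols = trace_columns(trace.branch_ids)
    df = trace.df
    if list(df.columns) != cols:
        raise FormatError("trace columns do not match the trace schema")
    with open(path, "w") as fh:
        fh.write(TRACE_MAGIC + "\n")
        for key in sorted(trace.metadata):
            fh.write(f"# {key}={trace.metadata[key]}\n")
        fh.write("\t".join(cols) + "\n")
        arr = df.to_numpy(dtype=float)
        for row in arr:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_trace(path: str):
    """Read a trace written by :func:`write_trace`; exact float round-trip."""
    from .mcmc_engine import PosteriorTrace  # local import: layering

    metadata: dict = {}
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != TRACE_MAGIC:
            raise FormatError(f"{path}: not a statedep trace file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("# "):
            key, _, val = line[2:].rstrip("\n").partition("=")
            metadata[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    beta_cols = [c for c in df.columns if c.startswith("beta_b")]
    branch_ids = [c[len("beta_") :] for c in beta_cols]
    expected = trace_columns(branch_ids)
    if list(df.columns) != expected:
        raise FormatError(f"{path}: trace column mismatch")
    if len(df) == 0:
        raise FormatError(f"{path}: empty trace")
    int_cols = ["generation", "delta", "n_gains", "n_losses"]
    df = df.astype({c: (np.int64 if c in int_cols else np.float64) for c in df.columns})
    return PosteriorTrace(df=df, branch_ids=branch_ids, metadata=metadata)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """MCMC run configuration.

    ``thinning=None`` auto-thins to at most ``target_samples`` retained samples
    per chain.  ``root_prior`` is the root-state prior of the discrete
    character: "stationary" (default) or a fixed state 0/1.  ``fix_delta``
    pins the reversible-jump indicator (None = sampled).  ``fix_q`` pins the
    CTMC rates at their initial values.
    """

    n_generations: int = 50_000
    n_chains: int = 2
    thinning: Optional[int] = None
    target_samples: int = 1000
    burnin_fraction: float = 0.25
    rng_seed: int = 0
    priors: Optional[object] = None  # statedep.mcmc_engine.Priors
    root_prior: object = "stationary"
    fix_delta: Optional[int] = None
    fix_q: bool = False
    likelihood_on: bool = True
    require_ultrametric: bool = False
    log10_transform: bool = False

    def __post_init__(self):
        if self.n_generations < 1:
            raise FormatError("n_generations must be >= 1")
        if not (0 <= self.burnin_fraction < 1):
            raise FormatError("burnin_fraction must be in [0, 1)")
        if self.thinning is not None and self.thinning < 1:
            raise FormatError("thinning must be >= 1")
        if self.priors is None:
            from .mcmc_engine import Priors

            self.priors = Priors()

    def resolved_thinning(self) -> int:
        post = int(self.n_generations * (1.0 - self.burnin_fraction))
        if self.thinning is not None:
            return self.thinning
        return max(1, post // self.target_samples)

    def n_retained(self) -> int:
        """floor((n_generations * (1 - burnin)) / thinning), per chain."""
        post = int(self.n_generations * (1.0 - self.burnin_fraction))
        return post // self.resolved_thinning()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priors"] = self.priors.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        from .mcmc_engine import Priors

        d = dict(d)
        pri = d.pop("priors", None)
        cfg = cls(**d)
        if pri is not None:
            cfg.priors = Priors.from_dict(pri) if isinstance(pri, dict) else pri
        return cfg

    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def read_run_config(path: str) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise FormatError(f"{path}: run config must be a YAML mapping")
    return RunConfig.from_dict(d)


def write_run_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
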