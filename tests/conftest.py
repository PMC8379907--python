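"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from statedep.io_formats import PhyloTree


@pytest.fixture
def cherry():
    return PhyloTree.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return PhyloTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def single_branch():
    """Root with a single tip child at distance 1 (for branch-level CTMC tests)."""
    return PhyloTree(np.array([-1, 0]), np.array([0.0, 1.0]), [None, "A"])


def random_tree(rng: np.random.Generator, n_tips: int) -> PhyloTree:
    """Random tree via the Yule simulator with randomized branch lengths."""
    from statedep.synthetic_data import simulate_yule

    tree = simulate_yule(n_tips, 1.0, rng)
    blen = tree.blen.copy()
    blen[1:] *= rng.uniform(0.2, 2.0, tree.n_nodes - 1)
    return PhyloTree(tree.parent, blen, tree.labels)


def tip_path_sets(tree: PhyloTree):
    paths = []
    for tip in tree.tip_indices:
        s = set()
        node = int(tip)
        while node != 0:
            s.add(node)
            node = int(tree.parent[node])
        paths.append(s)
    return paths


def dense_reml_oracle(tree: PhyloTree, tipvals: np.ndarray, v: np.ndarray,
                      Sigma: np.ndarray) -> float:
    """REML log-likelihood from the dense tip covariance (independent route).

    Builds C[i, j] = sum of effective lengths on the shared root path of tips
    i and j, evaluates the full (n*k)-dimensional normal density at the GLS
    root estimate, and subtracts the density of the root estimator at its
    mean -- the standard full-vs-REML decomposition.  Shares no code with the
    pruning implementation.
    """
    from scipy.stats import multivariate_normal

    Sigma = np.atleast_2d(Sigma)
    paths = tip_path_sets(tree)
    nt = len(paths)
    C = np.zeros((nt, nt))
    for i in range(nt):
        for j in range(nt):
            C[i, j] = sum(v[x] for x in paths[i] & paths[j])
    Cinv = np.linalg.inv(C)
    one = np.ones(nt)
    u_root = 1.0 / (one @ Cinv @ one)
    Y = np.atleast_2d(tipvals)
    if Y.shape[0] == 1 and nt > 1:
        Y = Y.T
    k = Sigma.shape[0]
    mu = u_root * (one @ Cinv @ Y)  # GLS root estimate, shape (k,)
    resid = (Y - mu).reshape(-1)  # row-major vec -> cov = kron(C, Sigma)
    cov = np.kron(C, Sigma)
    full = multivariate_normal.logpdf(resid, mean=np.zeros(nt * k), cov=cov,
                                      allow_singular=False)
    root_at_mean = -0.5 * (k * np.log(2 * np.pi) + k * np.log(u_root)
                           + np.linalg.slogdet(Sigma)[1])
    return float(full - root_at_mean)
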