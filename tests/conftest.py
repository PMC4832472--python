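"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's vectorized code paths:
likelihoods are recomputed by direct loops over the observation model,
ancestry by walking parent pointers, and tree spaces by exhaustive Prüfer
enumeration, so that agreement between oracle and implementation is a real
cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from clonetree import ClonalTree, ErrorModel, GenotypeMatrix
from clonetree.genotype_io import NA


# ---------------------------------------------------------------------------
# independent likelihood oracle (direct loops, linear-space products)
# ---------------------------------------------------------------------------

def obs_prob(d: int, delta: int, E: ErrorModel) -> float:
    """Single-call probability table, written out case by case."""
    if d == NA:
        return 1.0
    if delta == 0:
        return E.alpha if d == 1 else 1.0 - E.alpha
    return 1.0 - E.beta if d == 1 else E.beta


def is_ancestor_or_self(T: ClonalTree, c: int, x: int) -> bool:
    """Oracle ancestry: walk parent pointers from ``x`` up to the root."""
    while True:
        if x == c:
            return True
        if x == 1:
            return False
        x = int(T.parent[x])


def brute_force_known_theta(D: GenotypeMatrix, T: ClonalTree, theta: dict[str, int],
                            E: ErrorModel) -> float:
    total = 0.0
    for l, site in enumerate(D.sites):
        for k in range(D.n_cells):
            delta = int(is_ancestor_or_self(T, theta[site], int(T.assignment[k])))
            total += math.log(obs_prob(int(D.values[k, l]), delta, E))
    return total


def brute_force_marginal(D: GenotypeMatrix, T: ClonalTree, E: ErrorModel) -> float:
    """Explicit sum over every per-site mutation origin."""
    N = T.n_clones
    total = 0.0
    for l in range(D.n_sites):
        site_sum = 0.0
        for c in range(2, N + 1):
            prod = 1.0
            for k in range(D.n_cells):
                delta = int(is_ancestor_or_self(T, c, int(T.assignment[k])))
                prod *= obs_prob(int(D.values[k, l]), delta, E)
            site_sum += prod
        total += math.log(site_sum)
    return total - D.n_sites * math.log(N - 1)


# ---------------------------------------------------------------------------
# exhaustive tree enumeration (Prüfer sequences, rooted at clone 1)
# ---------------------------------------------------------------------------

def tree_from_prufer(seq: tuple[int, ...], n_nodes: int) -> np.ndarray:
    """Labeled tree on nodes 1..n_nodes from a Prüfer sequence, as an
    undirected edge list turned into a parent array rooted at node 1."""
    degree = {v: 1 for v in range(1, n_nodes + 1)}
    for v in seq:
        degree[v] += 1
    edges = []
    seq_list = list(seq)
    leaves = sorted(v for v in degree if degree[v] == 1)
    for v in seq_list:
        leaf = leaves.pop(0)
        edges.append((leaf, v))
        degree[v] -= 1
        if degree[v] == 1:
            import bisect

            bisect.insort(leaves, v)
    edges.append((leaves[0], leaves[1]))
    # orient away from root 1 by BFS
    adj: dict[int, list[int]] = {v: [] for v in range(1, n_nodes + 1)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent = np.zeros(n_nodes + 1, dtype=np.int64)
    seen = {1}
    queue = [1]
    while queue:
        u = queue.pop()
        for w in adj[u]:
            if w not in seen:
                seen.add(w)
                parent[w] = u
                queue.append(w)
    return parent


def enumerate_cell_trees(cells: tuple[str, ...]) -> list[ClonalTree]:
    """All labeled trees on root + one clone per cell ((n+1)^(n-1) of them)."""
    n_nodes = len(cells) + 1
    assignment = np.arange(2, n_nodes + 1, dtype=np.int64)
    if n_nodes == 2:
        return [ClonalTree(np.array([0, 0, 1]), assignment, cells)]
    trees = []
    for seq in itertools.product(range(1, n_nodes + 1), repeat=n_nodes - 2):
        parent = tree_from_prufer(seq, n_nodes)
        trees.append(ClonalTree(parent, assignment, cells))
    return trees


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_tree(rng: np.random.Generator, n_clones: int, n_cells: int,
                allow_unobserved: bool = True) -> ClonalTree:
    """Random clonal tree; some clones may end up cell-free (unobserved)."""
    N = n_clones + 1
    parent = np.zeros(N + 1, dtype=np.int64)
    for c in range(2, N + 1):
        parent[c] = rng.integers(1, c)
    if allow_unobserved and n_clones > 1:
        # leave a random subset of clones cell-free
        k = int(rng.integers(1, n_clones))
        holders = sorted(rng.choice(np.arange(2, N + 1), size=k, replace=False))
    else:
        holders = list(range(2, N + 1))
    assignment = np.array(
        [holders[i] if i < len(holders) else rng.choice(holders) for i in range(n_cells)],
        dtype=np.int64,
    )
    cells = tuple(f"c{i}" for i in range(n_cells))
    return ClonalTree(parent, assignment, cells)


def random_genotypes(rng: np.random.Generator, n_cells: int, n_sites: int,
                     p_na: float = 0.2) -> GenotypeMatrix:
    values = rng.choice(
        np.array([0, 1, NA], dtype=np.int8),
        size=(n_cells, n_sites),
        p=[(1 - p_na) / 2, (1 - p_na) / 2, p_na],
    )
    return GenotypeMatrix(
        tuple(f"c{i}" for i in range(n_cells)),
        tuple(f"s{j}" for j in range(n_sites)),
        values,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)
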