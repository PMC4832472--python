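"""Evaluation measures for comparing clonal lineage trees.

Three complementary views of reconstruction quality:

* clustering of cells into clones — V-measure (harmonic mean of homogeneity
  and completeness of the partition);
* overall tree shape — the pairwise cell shortest-path distance: both trees
  get an extra cell anchored in the root (so the root position matters even
  when it holds no cells), the edge distance between the clones of every
  cell pair is tabulated, and the absolute differences of the two tables
  are summed over all unordered pairs;
* mutation ordering — the fraction of correctly recovered pairwise mutation
  orders and mutual exclusivities, for comparison against methods that
  place mutations rather than cells.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.metrics import v_measure_score

from .tree import ClonalTree, ancestry

__all__ = [
    "cell_pair_distances",
    "shortest_path_distance",
    "v_measure",
    "mutation_order_accuracy",
]

#: Identifier of the synthetic cell anchored in the root for tree comparison.
ROOT_CELL = "__root__"


def _clone_distance_matrix(T: ClonalTree) -> np.ndarray:
    """Edge distances between all clone pairs via depths and ancestry."""
    A = ancestry(T)
    depth = T.depths()
    N = T.n_clones
    dist = np.zeros((N + 1, N + 1), dtype=np.int64)
    for a in range(1, N + 1):
        common = A[:, a][:, None] & A[:, a:]  # common ancestors of (a, b>=a)
        lca_depth = np.where(common[1:], depth[1:, None], -1).max(axis=0)
        dist[a, a:] = depth[a] + depth[a:] - 2 * lca_depth
        dist[a:, a] = dist[a, a:]
    return dist


def cell_pair_distances(T: ClonalTree) -> tuple[list[str], np.ndarray]:
    """Shortest-path distances between all cells, plus a root-anchored cell.

    Returns ``(labels, matrix)`` where labels start with the synthetic root
    cell followed by the tree's cells in sorted order.  Two cells in the
    same clone are at distance 0; otherwise the distance is the number of
    edges between their clones, direction ignored.
    """
    order = sorted(T.cells)
    clone_of = dict(zip(T.cells, T.assignment))
    clones = np.array([1] + [clone_of[c] for c in order], dtype=np.int64)
    D = _clone_distance_matrix(T)
    return [ROOT_CELL] + order, D[np.ix_(clones, clones)]


def shortest_path_distance(T1: ClonalTree, T2: ClonalTree, normalized: bool = False) -> float:
    """Pairwise cell shortest-path distance between two trees on the same cells.

    Sum over all unordered pairs of cells (root cell included) of the
    absolute difference of their shortest-path distances in the two trees.
    With ``normalized=True`` the sum is divided by the number of pairs
    summed, i.e. ``(n + 1) n / 2`` for ``n`` cells plus the root cell.
    """
    if set(T1.cells) != set(T2.cells):
        raise ValueError("trees must be built on the same cell set")
    labels, D1 = cell_pair_distances(T1)
    _, D2 = cell_pair_distances(T2)
    iu = np.triu_indices(len(labels), k=1)
    total = float(np.abs(D1[iu] - D2[iu]).sum())
    if normalized:
        total /= len(iu[0])
    return total


def v_measure(predicted: dict[str, int], truth: dict[str, int]) -> float:
    """V-measure of a predicted cell partition against the true one.

    Harmonic mean of homogeneity and completeness; 1.0 iff the partitions
    are identical up to relabeling.  Inputs map cell identifiers to cluster
    labels and must cover the same cells.
    """
    if set(predicted) != set(truth):
        raise ValueError("cell sets of the two partitions differ")
    cells = sorted(truth)
    return float(
        v_measure_score([truth[c] for c in cells], [predicted[c] for c in cells])
    )


def _pair_relation(A: np.ndarray, ca: int, cb: int) -> str:
    """Relation of two origin clones: 'upstream', 'downstream', 'same', 'exclusive'."""
    if ca == cb:
        return "same"
    if A[ca, cb]:
        return "upstream"
    if A[cb, ca]:
        return "downstream"
    return "exclusive"


def mutation_order_accuracy(
    pred_tree: ClonalTree,
    pred_theta: dict[str, int],
    true_tree: ClonalTree,
    true_theta: dict[str, int],
) -> float:
    """Accuracy of inferred pairwise mutation orders against the truth.

    Over mutation pairs whose true origins are *different* clones, averages

    1. the fraction of truly ordered pairs (one origin a strict ancestor of
       the other) whose order is reproduced, and
    2. the fraction of truly mutually exclusive pairs (origins on separate
       branches) recovered as mutually exclusive.

    Returns NaN when the truth has no mutually exclusive pair (e.g. a linear
    tree), where the measure is undefined.  Both trees must place every
    shared site.
    """
    sites = sorted(true_theta)
    missing = [s for s in sites if s not in pred_theta]
    if missing:
        raise ValueError(f"prediction lacks placements for {len(missing)} site(s)")
    A1, A2 = ancestry(pred_tree), ancestry(true_tree)
    ordered_total = ordered_hit = 0
    excl_total = excl_hit = 0
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            rel_true = _pair_relation(A2, true_theta[a], true_theta[b])
            if rel_true == "same":
                continue
            rel_pred = _pair_relation(A1, pred_theta[a], pred_theta[b])
            if rel_true == "exclusive":
                excl_total += 1
                excl_hit += rel_pred == "exclusive"
            else:
                ordered_total += 1
                ordered_hit += rel_pred == rel_true
    if excl_total == 0:
        return math.nan
    exclusive_frac = excl_hit / excl_total
    if ordered_total == 0:
        return exclusive_frac
    return 0.5 * (ordered_hit / ordered_total + exclusive_frac)
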