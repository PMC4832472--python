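"""Three-step heuristic inference of the clonal lineage tree.

Step 1 (initial search) explores the space of *cell* lineage trees — every
cell its own clone — by steepest-ascent hill climbing over prune-and-regraft
neighborhoods, starting from the star tree.  The climb tolerates a bounded
number of non-improving moves and, when it stalls, backtracks to the best
previously scored but not yet expanded solutions, which is what keeps it out
of shallow local optima.

Step 2 tests for unobserved clones: latent branch-point clones with no
sampled cells.  An unobserved clone is inserted at each branch point of the
current tree, its position and child set are optimized by a restricted local
search, and the enlarged model is accepted only if it beats the smaller one
by a Bayes factor above the threshold ``epsilon`` (log-likelihood gain above
log epsilon, since the model prior is uniform).

Step 3 clusters cells into clones by greedily merging child clones into
their parents along tree edges, as long as the likelihood stays within a
factor 1/epsilon of the best clustering seen so far.  Latent clones left
without a branching role are pruned at the end.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genotype_io import GenotypeMatrix
from .likelihood import ErrorModel, TreeScorer
from .tree import (
    ClonalTree,
    ancestry,
    apply_move,
    insert_node_at_branch_point,
    merge_edge,
    neighbor_moves,
    prune_linear_unobserved,
    star_tree,
)

__all__ = [
    "SearchConfig",
    "InferenceResult",
    "initial_search",
    "add_unobserved_clones",
    "cluster_cells",
    "infer",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Knobs of the heuristic search.

    epsilon : Bayes factor threshold (> 1) for accepting an extra unobserved
        clone and for tolerating likelihood loss when clustering cells;
        10 corresponds to "strong evidence" on Jeffreys's scale.
    max_stall : consecutive non-improving moves the hill climb makes before
        backtracking.
    backtrack_pool : how many best not-yet-expanded previous solutions are
        revisited without any global improvement before the search stops.
    max_iter : hard cap on the number of scored trees.
    seed : recorded for provenance; the search itself is deterministic
        (ties break towards the earliest generated move).
    """

    epsilon: float = 10.0
    max_stall: int = 5
    backtrack_pool: int = 10
    max_iter: int = 200_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 1.0:
            raise ValueError("epsilon must exceed 1")
        if min(self.max_stall, self.backtrack_pool, self.max_iter) < 1:
            raise ValueError("search counters must be >= 1")

    @property
    def log_epsilon(self) -> float:
        return float(np.log(self.epsilon))


@dataclass(frozen=True)
class InferenceResult:
    """A scored tree plus the provenance of how it was found."""

    tree: ClonalTree
    loglik: float
    error_model: ErrorModel
    trace: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def extended(self, label: str, loglik: float) -> "InferenceResult":
        return replace(self, trace=self.trace + ((label, loglik),))


def _backtracking_search(
    scorer: TreeScorer,
    start: ClonalTree,
    cfg: SearchConfig,
    moves_fn=neighbor_moves,
    patience: int | None = None,
) -> tuple[ClonalTree, float, int]:
    """Best-first hill climb over tree moves with bounded patience.

    Repeatedly expands the highest-scoring solution whose neighborhood has
    not been fully explored — while the climb improves this is plain
    steepest ascent, and on a stall it automatically resumes from the best
    previously scored solution.  The search stops when no expansion has
    improved the best tree for ``max_stall * backtrack_pool`` rounds, the
    frontier is exhausted (small spaces end up searched completely), or
    ``max_iter`` trees have been scored.  Deterministic: ties break towards
    the earliest generated move.

    Returns the best tree, its exact log-likelihood and the number of trees
    scored.  Candidate ranking runs in fast (single precision) arithmetic;
    the winner is re-scored exactly.
    """
    start_ll = scorer.marginal_loglik(start)
    scored: set[bytes] = {start.key()}
    frontier: list[tuple[float, int, ClonalTree]] = []  # max-heap via -loglik
    tick = 0
    heapq.heappush(frontier, (-start_ll, tick, start))

    best_tree, best_ll = start, start_ll
    if patience is None:
        patience = cfg.max_stall * cfg.backtrack_pool
    no_improve = 0
    n_scored = 1

    while frontier and n_scored < cfg.max_iter and no_improve < patience:
        _, _, cur = heapq.heappop(frontier)
        A = ancestry(cur)
        pairs = [
            (mv, t)
            for mv in moves_fn(cur, A)
            if (t := apply_move(cur, *mv)).key() not in scored
        ]
        if not pairs:
            continue  # neighborhood fully explored; not a counted expansion
        moves = [p[0] for p in pairs]
        nbrs = [p[1] for p in pairs]
        lls = scorer.score_neighborhood(cur, moves, A)
        n_scored += len(nbrs)
        for t, ll in zip(nbrs, lls):
            scored.add(t.key())
            tick += 1
            heapq.heappush(frontier, (-float(ll), tick, t))
        i = int(np.argmax(lls))
        if lls[i] > best_ll:
            best_tree, best_ll = nbrs[i], float(lls[i])
            no_improve = 0
        else:
            no_improve += 1

    if n_scored >= cfg.max_iter:
        logger.warning("search hit the max_iter cap (%d trees)", cfg.max_iter)
    exact_ll = scorer.marginal_loglik(best_tree)
    if exact_ll < start_ll:
        return start, start_ll, n_scored
    return best_tree, exact_ll, n_scored


def initial_search(
    D: GenotypeMatrix, E: ErrorModel, cfg: SearchConfig | None = None
) -> InferenceResult:
    """Step 1: best cell lineage tree, by backtracking hill climb from the star."""
    cfg = cfg or SearchConfig()
    scorer = TreeScorer(D, E)
    start = star_tree(list(D.cells))
    start_ll = scorer.marginal_loglik(start)
    best_tree, best_ll, n_scored = _backtracking_search(scorer, start, cfg)
    logger.info("initial search: %d trees scored, best loglik %.4f", n_scored, best_ll)
    result = InferenceResult(best_tree, best_ll, E)
    result = result.extended("star", start_ll)
    return result.extended("initial_search", best_ll)


def _restricted_moves(T: ClonalTree, u: int, A: np.ndarray) -> list[tuple[int, int]]:
    """Prune-and-regraft moves that involve clone ``u``.

    Moves where ``u`` itself is relocated, where a child is taken away from
    ``u``, or where another clone is attached below ``u`` — together these
    optimize both the position and the child set of a freshly inserted
    unobserved clone.
    """
    return [
        (v, t)
        for v, t in neighbor_moves(T, A)
        if v == u or t == u or T.parent[v] == u
    ]


def _hill_climb_restricted(
    scorer: TreeScorer, T: ClonalTree, u: int, cfg: SearchConfig
) -> tuple[ClonalTree, float]:
    """Backtracking search over the ``u``-restricted neighborhood.

    The subproblem — placing a single latent node — has an O(N) move space,
    so the no-improvement patience is scaled down to ``3 * max_stall``
    rather than the full search's ``max_stall * backtrack_pool``.
    """
    tree, ll, _ = _backtracking_search(
        scorer, T, cfg,
        moves_fn=lambda t, A: _restricted_moves(t, u, A),
        patience=3 * cfg.max_stall,
    )
    return tree, ll


def add_unobserved_clones(
    res: InferenceResult,
    D: GenotypeMatrix,
    E: ErrorModel,
    cfg: SearchConfig | None = None,
) -> InferenceResult:
    """Step 2: grow the model with unobserved branch-point clones.

    For each branch point of the current tree, a latent clone adopting the
    branch point's children is inserted and locally optimized; the best
    enlarged model replaces the current one iff its log-likelihood gain
    exceeds log(epsilon).  Repeats until no insertion passes the threshold.
    """
    cfg = cfg or SearchConfig()
    scorer = TreeScorer(D, E)
    tree, ll = res.tree, res.loglik
    while True:
        n_children = tree.n_children()
        branch_points = [c for c in tree.clones if n_children[c] >= 2]
        best_cand: tuple[ClonalTree, float] | None = None
        for b in branch_points:
            for cand in insert_node_at_branch_point(tree, b):
                u = cand.n_clones
                cand, cand_ll = _hill_climb_restricted(scorer, cand, u, cfg)
                if best_cand is None or cand_ll > best_cand[1]:
                    best_cand = (cand, cand_ll)
        if best_cand is None or best_cand[1] - ll <= cfg.log_epsilon:
            break
        tree = best_cand[0]
        ll = scorer.marginal_loglik(tree)
        logger.info(
            "accepted unobserved clone: N=%d, loglik %.4f", tree.n_clones, ll
        )
        res = res.extended("add_unobserved_clone", ll)
    return replace(res, tree=tree, loglik=ll).extended("unobserved_clones_done", ll)


def cluster_cells(
    res: InferenceResult,
    D: GenotypeMatrix,
    E: ErrorModel,
    cfg: SearchConfig | None = None,
) -> InferenceResult:
    """Step 3: cluster cells into clones by merging along tree edges.

    Repeatedly applies the best child-into-parent merge while the resulting
    log-likelihood stays above the best clustering solution seen so far
    minus log(epsilon); merges into the root are never considered.  Finally
    prunes unobserved clones that are no longer branch points.
    """
    cfg = cfg or SearchConfig()
    scorer = TreeScorer(D, E)
    tree, ll = res.tree, res.loglik
    best_ll = ll
    while True:
        candidates: list[ClonalTree] = []
        for child in range(2, tree.n_clones + 1):
            parent = int(tree.parent[child])
            if parent == 1:
                continue
            candidates.append(merge_edge(tree, child, parent)[0])
        if not candidates:
            break
        lls = scorer.score_batch(candidates)
        i = int(np.argmax(lls))
        if lls[i] <= best_ll - cfg.log_epsilon:
            break
        tree, ll = candidates[i], float(lls[i])
        best_ll = max(best_ll, ll)
        res = res.extended("merge", ll)
    pruned, _ = prune_linear_unobserved(tree)
    ll = scorer.marginal_loglik(pruned)
    return replace(res, tree=pruned, loglik=ll).extended("clustering_done", ll)


def infer(
    D: GenotypeMatrix,
    E: ErrorModel | None = None,
    cfg: SearchConfig | None = None,
) -> InferenceResult:
    """Full inference: initial search, unobserved-clone testing, clustering.

    If no error model is given, the false positive and false negative rates
    are first estimated by grid maximum likelihood (see
    :func:`clonetree.params.estimate_parameters`), then the final tree is
    the one inferred at the selected rates.
    """
    cfg = cfg or SearchConfig()
    if E is None:
        from .params import default_grid, estimate_parameters

        _, res, _ = estimate_parameters(D, default_grid(), cfg)
        return res
    res = initial_search(D, E, cfg)
    res = add_unobserved_clones(res, D, E, cfg)
    return cluster_cells(res, D, E, cfg)
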