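"""Two-step simulator of clonal trees and noisy single-cell genotype matrices.

Step one draws a random clonal lineage tree: clones are attached one by one,
each choosing a uniformly random existing non-root clone as parent (clone 2
always hangs off the root).  If unobserved clones are requested, trees are
re-drawn until enough branch points (non-root clones with >= 2 children)
exist, and the unobserved clones are picked uniformly among them.  Every
observed clone receives one cell; remaining cells join observed clones with
probability proportional to current clone size, producing realistically
skewed clone sizes.

Step two draws the genotype matrix: each site's mutation origin is uniform
over non-root clones, true genotypes follow from ancestry (a cell carries
the mutation iff its clone is the origin or a descendant of it), and noise
is layered on in order: a fixed fraction of entries is masked as missing,
then a fraction alpha of unmutated non-missing entries flips to 1 and a
fraction beta of mutated non-missing entries flips to 0 (exact counts, not
i.i.d. coin flips, so small matrices hit the nominal rates).  Any site left
with no observed mutation receives one rescue false positive, mirroring the
fact that variant calling only reports sites seen mutated somewhere.
Finally the cell order is shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import NA, GenotypeMatrix
from .tree import ClonalTree, ancestry

__all__ = ["SimulationConfig", "GroundTruth", "simulate_tree", "simulate_genotypes", "simulate_dataset"]

_MAX_TREE_ATTEMPTS = 100_000


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the simulator.

    Defaults are the standard benchmark setting: ten clones, none
    unobserved, 20 cells, 200 sites, false positive rate 0.2, false
    negative rate 0.1 and 20% missing entries.
    """

    n_clones: int = 10          # tumor clones, root excluded
    n_unobserved: int = 0
    n_cells: int = 20
    n_sites: int = 200
    alpha: float = 0.2
    beta: float = 0.1
    p_missing: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("need at least one tumor clone")
        if not 0 <= self.n_unobserved < self.n_clones:
            raise ValueError("n_unobserved must be < n_clones")
        if self.n_cells < self.n_clones - self.n_unobserved:
            raise ValueError("need at least one cell per observed clone")
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        for name in ("alpha", "beta", "p_missing"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator knows and inference tries to recover."""

    tree: ClonalTree
    theta: dict[str, int]                    # site -> origin clone
    true_genotypes: np.ndarray = field(repr=False)  # (n_cells, n_sites) 0/1


def simulate_tree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> ClonalTree:
    """Draw a random clonal lineage tree with cells assigned to observed clones."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    c = cfg.n_clones
    for _ in range(_MAX_TREE_ATTEMPTS):
        parent = np.zeros(c + 2, dtype=np.int64)
        parent[2] = 1
        for node in range(3, c + 2):
            parent[node] = rng.integers(2, node)  # uniform over existing non-root
        if cfg.n_unobserved == 0:
            unobserved: list[int] = []
        else:
            counts = np.zeros(c + 2, dtype=np.int64)
            np.add.at(counts, parent[2:], 1)
            branch_points = [v for v in range(2, c + 2) if counts[v] >= 2]
            if len(branch_points) < cfg.n_unobserved:
                continue  # reject and re-draw the tree
            unobserved = sorted(
                rng.choice(branch_points, size=cfg.n_unobserved, replace=False)
            )
        observed = [v for v in range(2, c + 2) if v not in unobserved]
        assignment = np.empty(cfg.n_cells, dtype=np.int64)
        assignment[: len(observed)] = observed
        sizes = {v: 1 for v in observed}
        for k in range(len(observed), cfg.n_cells):
            weights = np.array([sizes[v] for v in observed], dtype=float)
            pick = observed[rng.choice(len(observed), p=weights / weights.sum())]
            assignment[k] = pick
            sizes[pick] += 1
        cells = tuple(f"cell{k + 1}" for k in range(cfg.n_cells))
        return ClonalTree(parent, assignment, cells)
    raise RuntimeError(
        f"could not draw a tree with {cfg.n_unobserved} unobserved clones in "
        f"{_MAX_TREE_ATTEMPTS} attempts; configuration likely infeasible"
    )


def _exact_count(fraction: float, total: int) -> int:
    return int(round(fraction * total))


def simulate_genotypes(
    tree: ClonalTree,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Draw a noisy observed genotype matrix for ``tree``.

    Noise is applied on disjoint entry sets in the order missing -> false
    positives -> false negatives, with exact counts (rounded fraction of the
    eligible entries).  Sites that end up with no observed mutant call get
    one rescue false positive in a random cell (preferring cells whose entry
    at that site is not missing).  Cell (row) order is randomized; cell
    identifiers travel with their rows, so the ground truth stays linked by
    identifier.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n, m = tree.n_cells, cfg.n_sites
    N = tree.n_clones
    sites = tuple(f"site{l + 1}" for l in range(m))

    origins = rng.integers(2, N + 1, size=m)
    A = ancestry(tree)
    true_genotypes = A[origins][:, tree.assignment].T.astype(np.int8)  # (n, m)

    obs = true_genotypes.astype(np.int8).copy()
    flat = obs.ravel()

    n_missing = _exact_count(cfg.p_missing, n * m)
    missing_idx = rng.choice(n * m, size=n_missing, replace=False)
    flat[missing_idx] = NA

    # flip fractions refer to the *true* genotype status, so the false
    # positive and false negative entry sets are disjoint by construction
    true_flat = true_genotypes.ravel()
    zero_idx = np.flatnonzero((flat != NA) & (true_flat == 0))
    n_fp = _exact_count(cfg.alpha, len(zero_idx))
    if n_fp:
        flat[rng.choice(zero_idx, size=n_fp, replace=False)] = 1

    one_idx = np.flatnonzero((flat != NA) & (true_flat == 1))
    n_fn = _exact_count(cfg.beta, len(one_idx))
    if n_fn:
        flat[rng.choice(one_idx, size=n_fn, replace=False)] = 0

    # variant calling never reports a site with no mutant observation
    for l in np.flatnonzero((obs == 1).sum(axis=0) == 0):
        callable_cells = np.flatnonzero(obs[:, l] != NA)
        k = rng.choice(callable_cells) if len(callable_cells) else rng.integers(n)
        obs[k, l] = 1

    order = rng.permutation(n)
    observed_matrix = GenotypeMatrix(
        tuple(tree.cells[k] for k in order), sites, obs[order]
    )
    theta = {site: int(c) for site, c in zip(sites, origins)}
    return observed_matrix, GroundTruth(tree, theta, true_genotypes)


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Convenience wrapper: draw tree and genotypes with one RNG stream."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg, rng)
    return simulate_genotypes(tree, cfg, rng)
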