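"""Three-step inference: hill climb, unobserved-clone testing, clustering."""

import math

import numpy as np
import pytest

from clonetree import (
    ClonalTree,
    ErrorModel,
    GenotypeMatrix,
    SearchConfig,
    SimulationConfig,
    add_unobserved_clones,
    ancestry,
    cluster_cells,
    infer,
    initial_search,
    marginal_loglik,
    shortest_path_distance,
    simulate_dataset,
    star_tree,
)
from clonetree.search import InferenceResult

from conftest import enumerate_cell_trees


def noise_free_matrix(T: ClonalTree, origins: np.ndarray) -> GenotypeMatrix:
    A = ancestry(T)
    values = A[origins][:, T.assignment].T.astype(np.int8)
    return GenotypeMatrix(T.cells, tuple(f"s{j}" for j in range(len(origins))), values)


@pytest.fixture
def branching_truth():
    """Root -> latent u -> {A, B}: two observed clones sharing trunk mutations.

    Clones: 1 root, 2/3 observed with two cells each, 4 latent branch point.
    Ten trunk sites originate in u, ten in A, ten in B.
    """
    parent = np.array([0, 0, 4, 4, 1])
    assignment = np.array([2, 2, 3, 3])
    T = ClonalTree(parent, assignment, ("a1", "a2", "b1", "b2"))
    origins = np.array([4] * 10 + [2] * 10 + [3] * 10)
    D = noise_free_matrix(T, origins)
    return T, D


class TestInitialSearch:
    def test_recovers_chain_from_noise_free_data(self):
        # 4-cell chain; exhaustive enumeration confirms the global optimum
        parent = np.array([0, 0, 1, 2, 3, 4])
        T = ClonalTree(parent, np.array([2, 3, 4, 5]), ("c0", "c1", "c2", "c3"))
        D = noise_free_matrix(T, np.array([2, 3, 4, 5, 3, 4]))
        E = ErrorModel(1e-3, 1e-3)
        res = initial_search(D, E)
        best = max(marginal_loglik(D, t, E) for t in enumerate_cell_trees(D.cells))
        assert res.loglik == pytest.approx(best, abs=1e-9)
        assert res.tree.key() == T.key()

    def test_two_cells_returns_space_optimum(self, rng):
        from conftest import random_genotypes

        D = random_genotypes(rng, 2, 6)
        E = ErrorModel(0.2, 0.1)
        res = initial_search(D, E)
        best = max(marginal_loglik(D, t, E) for t in enumerate_cell_trees(D.cells))
        assert res.loglik == pytest.approx(best, abs=1e-9)

    def test_never_below_star_tree(self, rng):
        from conftest import random_genotypes

        for _ in range(5):
            D = random_genotypes(rng, 5, 10, p_na=0.5)
            E = ErrorModel(0.3, 0.3)
            res = initial_search(D, E)
            assert res.loglik >= marginal_loglik(D, star_tree(list(D.cells)), E) - 1e-9

    def test_result_is_cell_tree(self, rng):
        from conftest import random_genotypes

        D = random_genotypes(rng, 4, 8)
        res = initial_search(D, ErrorModel(0.2, 0.2))
        assert res.tree.n_clones == D.n_cells + 1
        assert res.tree.observed()[2:].all()  # no unobserved non-root clones


class TestUnobservedClones:
    def test_pure_chain_has_nothing_to_insert(self):
        parent = np.array([0, 0, 1, 2])
        T = ClonalTree(parent, np.array([2, 3]), ("c0", "c1"))
        D = noise_free_matrix(T, np.array([2, 3]))
        E = ErrorModel(0.01, 0.01)
        res = InferenceResult(T, marginal_loglik(D, T, E), E)
        out = add_unobserved_clones(res, D, E)
        assert out.tree.key() == T.key()

    def test_recovers_latent_branch_clone(self, branching_truth):
        T_true, D = branching_truth
        E = ErrorModel(0.01, 0.01)
        res = initial_search(D, E)
        out = add_unobserved_clones(res, D, E)
        assert out.tree.n_clones == res.tree.n_clones + 1
        assert out.loglik - res.loglik > math.log(10)
        latent = out.tree.n_clones
        assert not out.tree.observed()[latent]

    def test_huge_epsilon_never_accepts(self, branching_truth):
        _, D = branching_truth
        E = ErrorModel(0.01, 0.01)
        cfg = SearchConfig(epsilon=1e300)  # log threshold beyond any possible gain
        res = initial_search(D, E, cfg)
        out = add_unobserved_clones(res, D, E, cfg)
        assert out.tree.key() == res.tree.key()


class TestClustering:
    def test_identical_cells_merge(self):
        values = np.array([[1, 1, 0, 0]] * 2 + [[1, 1, 1, 1]] * 1, dtype=np.int8)
        D = GenotypeMatrix(("c0", "c1", "c2"), ("s0", "s1", "s2", "s3"), values)
        E = ErrorModel(0.01, 0.01)
        res = infer(D, E)
        clone_of = dict(zip(res.tree.cells, res.tree.assignment))
        assert clone_of["c0"] == clone_of["c1"] != clone_of["c2"]

    def test_disjoint_mutation_sets_stay_separate(self):
        values = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        D = GenotypeMatrix(("c0", "c1"), ("s0", "s1", "s2", "s3"), values)
        res = infer(D, ErrorModel(0.01, 0.01))
        clone_of = dict(zip(res.tree.cells, res.tree.assignment))
        assert clone_of["c0"] != clone_of["c1"]

    def test_tight_epsilon_only_non_degrading_merges(self, rng):
        from conftest import random_genotypes

        D = random_genotypes(rng, 4, 12)
        E = ErrorModel(0.2, 0.2)
        cfg = SearchConfig(epsilon=1.0 + 1e-9)
        res = initial_search(D, E, cfg)
        out = cluster_cells(res, D, E, cfg)
        assert out.loglik >= res.loglik - 1e-6


class TestInfer:
    def test_toy_branching_pipeline_recovers_truth(self, branching_truth):
        T_true, D = branching_truth
        res = infer(D, ErrorModel(0.01, 0.01))
        assert shortest_path_distance(res.tree, T_true) == 0.0

    def test_single_cell_input(self):
        D = GenotypeMatrix(("c0",), ("s0", "s1"), np.array([[1, 1]], dtype=np.int8))
        res = infer(D, ErrorModel(0.1, 0.1))
        assert res.tree.n_clones == 2
        assert res.tree.observed()[2]

    def test_same_seed_reruns_are_identical(self):
        D, _ = simulate_dataset(SimulationConfig(n_clones=4, n_cells=8, n_sites=60, seed=5))
        E = ErrorModel(0.2, 0.1)
        r1, r2 = infer(D, E), infer(D, E)
        assert r1.tree.key() == r2.tree.key()
        assert r1.loglik == r2.loglik
        assert r1.trace == r2.trace

    def test_final_loglik_is_recomputable_from_scratch(self):
        D, _ = simulate_dataset(SimulationConfig(n_clones=5, n_cells=10, n_sites=80, seed=11))
        E = ErrorModel(0.2, 0.1)
        res = infer(D, E)
        assert res.loglik == pytest.approx(marginal_loglik(D, res.tree, E), abs=1e-9)

    def test_trace_respects_stage_monotonicity(self):
        D, _ = simulate_dataset(SimulationConfig(n_clones=4, n_cells=8, n_sites=60, seed=2))
        E = ErrorModel(0.2, 0.1)
        cfg = SearchConfig()
        res = infer(D, E, cfg)
        stages = dict()
        running_best = -np.inf
        for label, ll in res.trace:
            stages.setdefault(label, []).append(ll)
            if label == "add_unobserved_clone":
                assert ll - running_best > cfg.log_epsilon
            if label == "merge":
                assert ll > running_best - cfg.log_epsilon - 1e-6
            running_best = max(running_best, ll)
        assert stages["initial_search"][0] >= stages["star"][0]

    def test_global_optimum_rate_on_small_noise_free_instances(self, rng):
        # 30 replicates on 4 cells; the acceptance suite runs the full 100
        trees = enumerate_cell_trees(("c0", "c1", "c2", "c3"))
        # small but resolvable rates: tree distinctions stay far above the
        # search's single-precision ranking resolution
        E = ErrorModel(1e-3, 1e-3)
        hits = 0
        for _ in range(30):
            truth = trees[int(rng.integers(len(trees)))]
            origins = rng.integers(2, 6, size=8)
            D = noise_free_matrix(truth, origins)
            res = initial_search(D, E)
            best = max(marginal_loglik(D, t, E) for t in trees)
            hits += res.loglik >= best - 1e-9
        assert hits >= int(0.95 * 30)
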