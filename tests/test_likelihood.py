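"""Observation model and marginal tree likelihood against brute-force oracles."""

import math

import numpy as np
import pytest

from clonetree import (
    ClonalTree,
    ErrorModel,
    GenotypeMatrix,
    known_theta_loglik,
    marginal_loglik,
    single_obs_loglik,
    site_clone_loglik,
    star_tree,
)
from clonetree.genotype_io import NA
from clonetree.likelihood import TreeScorer

from conftest import (
    brute_force_known_theta,
    brute_force_marginal,
    enumerate_cell_trees,
    random_genotypes,
    random_tree,
)


def matrix(values, cells=None, sites=None):
    arr = np.array(values, dtype=np.int8)
    cells = cells or tuple(f"c{i}" for i in range(arr.shape[0]))
    sites = sites or tuple(f"s{j}" for j in range(arr.shape[1]))
    return GenotypeMatrix(cells, sites, arr)


def chain_tree(n_cells):
    parent = np.arange(n_cells + 2, dtype=np.int64) - 1
    parent[1] = 0
    return ClonalTree(
        parent, np.arange(2, n_cells + 2), tuple(f"c{i}" for i in range(n_cells))
    )


class TestSingleObservation:
    E = ErrorModel(0.2, 0.1)

    @pytest.mark.parametrize("delta", [0, 1])
    def test_missing_call_is_certain(self, delta):
        assert single_obs_loglik(NA, delta, self.E) == 0.0

    def test_error_and_agreement_cases(self):
        assert single_obs_loglik(1, 0, self.E) == pytest.approx(math.log(0.2))
        assert single_obs_loglik(0, 1, self.E) == pytest.approx(math.log(0.1))
        assert single_obs_loglik(0, 0, self.E) == pytest.approx(math.log(0.8))
        assert single_obs_loglik(1, 1, self.E) == pytest.approx(math.log(0.9))

    def test_zero_rates_give_minus_infinity_on_mismatch(self):
        E0 = ErrorModel(0.0, 0.0)
        assert single_obs_loglik(1, 0, E0) == -math.inf
        assert single_obs_loglik(0, 0, E0) == 0.0


class TestSiteCloneTable:
    def test_single_cell_single_site(self):
        S = site_clone_loglik(matrix([[1]]), chain_tree(1), ErrorModel(0.2, 0.1))
        assert S.shape == (1, 1)
        assert S[0, 0] == pytest.approx(math.log(0.9))

    def test_all_missing_matrix_scores_zero_everywhere(self):
        with pytest.warns(UserWarning):
            D = matrix([[NA, NA], [NA, NA]])
        S = site_clone_loglik(D, star_tree(["c0", "c1"]), ErrorModel(0.2, 0.1))
        assert np.all(S == 0.0)

    def test_entries_are_log_probabilities(self, rng):
        D = random_genotypes(rng, 5, 8)
        T = random_tree(rng, 4, 5)
        S = site_clone_loglik(D, T, ErrorModel(0.13, 0.21))
        assert np.all(S <= 0.0)

    def test_agrees_with_per_entry_double_loop(self, rng):
        from conftest import is_ancestor_or_self, obs_prob

        for _ in range(20):
            D = random_genotypes(rng, 5, 8)
            T = random_tree(rng, 4, 5)
            E = ErrorModel(float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.05, 0.4)))
            S = site_clone_loglik(D, T, E)
            for l in range(8):
                for c in range(2, T.n_clones + 1):
                    expected = sum(
                        math.log(
                            obs_prob(
                                int(D.values[k, l]),
                                int(is_ancestor_or_self(T, c, int(T.assignment[k]))),
                                E,
                            )
                        )
                        for k in range(5)
                    )
                    assert S[l, c - 2] == pytest.approx(expected, abs=1e-10)


class TestMarginal:
    def test_single_na_observation_is_certain(self):
        with pytest.warns(UserWarning):
            D = matrix([[NA]])
        assert marginal_loglik(D, chain_tree(1), ErrorModel(0.2, 0.1)) == 0.0

    def test_single_mutated_cell_collapses_to_one_minus_beta(self):
        D = matrix([[1]])
        ll = marginal_loglik(D, chain_tree(1), ErrorModel(0.2, 0.1))
        assert ll == pytest.approx(math.log(0.9))

    def test_matches_explicit_origin_sum_on_printed_chain(self):
        # three cells on a chain, four sites written out by hand
        D = matrix([[1, 0, 0, NA], [1, 1, 0, 0], [1, 1, 1, 1]])
        T = chain_tree(3)
        E = ErrorModel(0.2, 0.1)
        assert marginal_loglik(D, T, E) == pytest.approx(
            brute_force_marginal(D, T, E), abs=1e-12
        )

    def test_known_theta_averaged_equals_marginal(self, rng):
        import itertools

        for _ in range(5):
            D = random_genotypes(rng, 3, 3)
            T = random_tree(rng, 3, 3)
            E = ErrorModel(0.25, 0.15)
            total = 0.0
            origins = range(2, T.n_clones + 1)
            for combo in itertools.product(origins, repeat=D.n_sites):
                theta = dict(zip(D.sites, combo))
                total += math.exp(known_theta_loglik(D, T, theta, E))
            total /= (T.n_clones - 1) ** D.n_sites
            assert marginal_loglik(D, T, E) == pytest.approx(math.log(total), abs=1e-10)

    def test_invariant_under_cell_and_site_permutation(self, rng):
        D = random_genotypes(rng, 6, 9)
        T = random_tree(rng, 5, 6)
        E = ErrorModel(0.2, 0.1)
        base = marginal_loglik(D, T, E)
        perm_c = rng.permutation(6)
        perm_s = rng.permutation(9)
        D2 = GenotypeMatrix(
            tuple(D.cells[i] for i in perm_c),
            tuple(D.sites[j] for j in perm_s),
            D.values[np.ix_(perm_c, perm_s)],
        )
        T2 = ClonalTree(T.parent, T.assignment[perm_c], D2.cells)
        assert marginal_loglik(D2, T2, E) == pytest.approx(base, abs=1e-9)

    def test_truth_is_global_optimum_on_noise_free_data(self, rng):
        # exhaustively over all labeled cell trees on 4 cells
        cells = ("c0", "c1", "c2", "c3")
        trees = enumerate_cell_trees(cells)
        # exact-zero rates keep equally-explaining trees exactly tied
        E = ErrorModel(0.0, 0.0)
        for _ in range(5):
            truth = trees[int(rng.integers(len(trees)))]
            from clonetree import ancestry

            A = ancestry(truth)
            origins = rng.integers(2, truth.n_clones + 1, size=6)
            D = GenotypeMatrix(
                cells,
                tuple(f"s{j}" for j in range(6)),
                A[origins][:, truth.assignment].T.astype(np.int8),
            )
            ll_truth = marginal_loglik(D, truth, E)
            assert ll_truth == pytest.approx(
                max(marginal_loglik(D, t, E) for t in trees), abs=1e-12
            )

    def test_linear_unobserved_clone_duplicates_child_pattern(self):
        # 1 -> 2 -> 3 with one cell in each tumor clone; insert latent u
        # between root and 2: its predicted pattern equals clone 2's, every
        # other origin's column is unchanged
        D = matrix([[1, 0], [1, 1]])
        T = chain_tree(2)
        E = ErrorModel(0.2, 0.1)
        T_ext = ClonalTree(np.array([0, 0, 4, 2, 1]), np.array([2, 3]), D.cells)
        S, S_ext = site_clone_loglik(D, T, E), site_clone_loglik(D, T_ext, E)
        np.testing.assert_allclose(S_ext[:, [0, 1]], S)  # clones 2, 3 unchanged
        np.testing.assert_allclose(S_ext[:, 2], S[:, 0])  # u duplicates clone 2

    def test_no_overflow_on_large_instances(self, rng):
        D = random_genotypes(rng, 20, 10_000, p_na=0.1)
        T = random_tree(rng, 99, 20)
        ll = marginal_loglik(D, T, ErrorModel(0.2, 0.1))
        assert np.isfinite(ll)

    def test_rejects_cell_set_mismatch_and_trivial_tree(self):
        D = matrix([[1]])
        with pytest.raises(ValueError, match="cell set"):
            marginal_loglik(D, chain_tree(2), ErrorModel(0.1, 0.1))


class TestKnownTheta:
    def test_noise_free_generative_data_is_certain(self):
        T = chain_tree(2)  # cells c0 in clone 2, c1 in clone 3
        D = matrix([[1, 0], [1, 1]])
        theta = {"s0": 2, "s1": 3}
        assert known_theta_loglik(D, T, theta, ErrorModel(0.0, 0.0)) == 0.0

    def test_root_origin_rejected(self):
        D = matrix([[1]])
        with pytest.raises(ValueError, match="non-root"):
            known_theta_loglik(D, chain_tree(1), {"s0": 1}, ErrorModel(0.1, 0.1))

    def test_single_mismatch_costs_the_likelihood_ratio(self):
        T = chain_tree(2)
        E = ErrorModel(0.2, 0.1)
        theta = {"s0": 2}
        matched = known_theta_loglik(matrix([[1, ], [1, ]]), T, theta, E)
        flipped = known_theta_loglik(matrix([[1, ], [0, ]]), T, theta, E)
        assert matched - flipped == pytest.approx(math.log(0.9 / 0.1))

    def test_agrees_with_brute_force(self, rng):
        for _ in range(10):
            D = random_genotypes(rng, 4, 6)
            T = random_tree(rng, 4, 4)
            E = ErrorModel(0.3, 0.2)
            theta = {s: int(rng.integers(2, T.n_clones + 1)) for s in D.sites}
            assert known_theta_loglik(D, T, theta, E) == pytest.approx(
                brute_force_known_theta(D, T, theta, E), abs=1e-10
            )


class TestScorerBatch:
    def test_batch_matches_single_tree_scoring(self, rng):
        D = random_genotypes(rng, 6, 15)
        E = ErrorModel(0.2, 0.1)
        scorer = TreeScorer(D, E)
        trees = [random_tree(rng, 5, 6) for _ in range(20)]
        batch = scorer.score_batch(trees)
        for t, ll in zip(trees, batch):
            assert ll == pytest.approx(scorer.marginal_loglik(t), abs=1e-9)

    def test_neighborhood_scores_match_independent_rescoring(self, rng):
        from clonetree.tree import ancestry, apply_move, neighbor_moves

        D = random_genotypes(rng, 6, 15)
        E = ErrorModel(0.2, 0.1)
        scorer = TreeScorer(D, E)
        T = random_tree(rng, 6, 6)
        moves = neighbor_moves(T)
        fast = scorer.score_neighborhood(T, moves, ancestry(T))
        for mv, ll in zip(moves, fast):
            assert ll == pytest.approx(
                scorer.marginal_loglik(apply_move(T, *mv)), abs=1e-3
            )

    def test_exact_zero_rates_are_legal_in_batch(self, rng):
        D = random_genotypes(rng, 4, 6, p_na=0.0)
        scorer = TreeScorer(D, ErrorModel(0.0, 0.0))
        trees = [random_tree(rng, 3, 4) for _ in range(5)]
        lls = scorer.score_batch(trees)
        assert not np.isnan(lls).any()
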