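"""Marginal likelihood of a clonal lineage tree given noisy genotype calls.

The observation model: every call ``d_kl`` is an independent noisy draw of
the true genotype ``delta_kl`` predicted by the tree, with a global false
positive rate ``alpha`` (P(1 | true 0)) and false negative rate ``beta``
(P(0 | true 1)); a missing call (NA) is the uninformative event {0, 1} and
contributes probability 1.

For a tree T with N clones, a mutation at site ``l`` is assumed to originate
in exactly one non-root clone ``theta_l``, a priori uniform over the N - 1
candidates.  Given the origin, the true genotype of cell ``k`` is 1 iff the
cell's clone is the origin or one of its descendants.  Marginalizing the
unknown origins gives the tree likelihood

    P(D | T) = (N - 1)^-m  prod_l  sum_{c=2..N}  prod_k P(d_kl | delta = A[c, c(k)])

computed here entirely in log space.  ``SiteCloneLogLik`` is the inner
``m x (N - 1)`` table of per-site, per-origin log-likelihood terms; it is
also the sufficient input for the mutation-placement posterior.

The :class:`TreeScorer` caches the data-dependent parts so the tree search
can score large batches of candidate trees with a single matrix product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

try:  # optional JIT acceleration of the neighborhood-scoring kernel
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

from .genotype_io import NA, GenotypeMatrix
from .tree import ClonalTree, ancestry

__all__ = [
    "ErrorModel",
    "single_obs_loglik",
    "site_clone_loglik",
    "marginal_loglik",
    "known_theta_loglik",
    "TreeScorer",
]

# Matmul-safe stand-in for log(0): avoids 0 * -inf = nan inside the batched
# products; entries this small are mapped back to -inf afterwards.
_LOG_ZERO = -1e30


def _logsumexp(S: np.ndarray, axis: int) -> np.ndarray:
    """Stable log-sum-exp; rows that are entirely -inf reduce to -inf."""
    mx = np.max(S, axis=axis, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(divide="ignore"):
        return np.log(np.exp(S - mx).sum(axis=axis)) + np.squeeze(mx, axis=axis)


def _score_moves_kernel_py(parent, moves, R_clone, base_site, log_norm):
    """Reference implementation of the fused neighborhood scorer.

    For each prune-and-regraft move, the per-site, per-origin scores S[c, l]
    equal ``base_site[l]`` (every cell predicted unmutated) plus the sum of
    the per-clone adjustment rows ``R_clone[d]`` over all clones ``d`` in the
    subtree of the origin ``c``; subtree sums are accumulated by walking each
    clone's ancestor chain, and the per-site log-sum-exp over origins is
    folded in directly.
    """
    N = len(parent) - 1
    m = R_clone.shape[1]
    out = np.empty(len(moves))
    parent = parent.copy()
    for i, (v, t) in enumerate(moves):
        old = parent[v]
        parent[v] = t
        CR = np.zeros((N + 1, m), dtype=np.float32)
        for d in range(2, N + 1):
            x = d
            while True:
                if x >= 2:
                    CR[x] += R_clone[d]
                if x == 1:
                    break
                x = parent[x]
        S = CR[2:]
        mx = S.max(axis=0)
        with np.errstate(divide="ignore"):
            per_site = mx + np.log(np.exp(S - mx).sum(axis=0))
        out[i] = float((per_site + base_site).sum(dtype=np.float64)) - log_norm
        parent[v] = old
    return out


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _score_moves_kernel_nb(parent, moves, R_clone, base_site, log_norm):  # pragma: no cover - numerics covered via wrapper tests
        # S[c] (origin-c per-site scores, up to base_site) equals the subtree
        # sum of R_clone at c.  A move only shifts the moved subtree's total
        # along the old and new ancestor chains, so the table is maintained
        # incrementally: save the touched rows, adjust, score, restore.
        N = len(parent) - 1
        m = R_clone.shape[1]
        out = np.empty(len(moves), dtype=np.float64)

        # depth-ordered bottom-up pass builds the subtree-sum table CR
        depth = np.zeros(N + 1, dtype=np.int64)
        for c in range(2, N + 1):
            x = c
            while x != 1:
                x = parent[x]
                depth[c] += 1
        order = np.argsort(-depth)
        CR = R_clone.copy()
        for idx in range(N + 1):
            c = order[idx]
            if c >= 2:
                p = parent[c]
                for l in range(m):
                    CR[p, l] += CR[c, l]

        touched = np.empty(2 * N + 2, dtype=np.int64)
        saved = np.empty((2 * N + 2, m), dtype=np.float32)
        for i in range(len(moves)):
            v, t = moves[i, 0], moves[i, 1]
            ntouch = 0
            x = parent[v]
            while x != 1:
                touched[ntouch] = x
                ntouch += 1
                x = parent[x]
            x = t
            while x != 1:
                touched[ntouch] = x
                ntouch += 1
                x = parent[x]
            for j in range(ntouch):
                r = touched[j]
                for l in range(m):
                    saved[j, l] = CR[r, l]
            x = parent[v]
            while x != 1:
                for l in range(m):
                    CR[x, l] -= CR[v, l]
                x = parent[x]
            x = t
            while x != 1:
                for l in range(m):
                    CR[x, l] += CR[v, l]
                x = parent[x]
            ll = 0.0
            for l in range(m):
                mx = CR[2, l]
                for c in range(3, N + 1):
                    if CR[c, l] > mx:
                        mx = CR[c, l]
                acc = 0.0
                for c in range(2, N + 1):
                    diff = CR[c, l] - mx
                    if diff > -25.0:  # exp underflows the float32 sum anyway
                        acc += np.exp(diff)
                ll += mx + np.log(acc) + base_site[l]
            out[i] = ll - log_norm
            for j in range(ntouch - 1, -1, -1):
                r = touched[j]
                for l in range(m):
                    CR[r, l] = saved[j, l]
        return out


@dataclass(frozen=True)
class ErrorModel:
    """Global genotyping error rates of the binarized call matrix.

    alpha : false positive rate, P(observe 1 | true genotype 0).
    beta  : false negative rate, P(observe 0 | true genotype 1).  Dominated
            by allele dropout in single-cell data, hence typically >> alpha
            before filtering; both live in [0, 1).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha < 1.0 and 0.0 <= self.beta < 1.0):
            raise ValueError(f"error rates must lie in [0, 1): {self}")

    def log_terms(self) -> tuple[float, float, float, float]:
        """(log(1-a), log a, log b, log(1-b)) with log 0 as a finite sentinel."""

        def safe_log(x: float) -> float:
            return math.log(x) if x > 0.0 else _LOG_ZERO

        return (
            safe_log(1.0 - self.alpha),
            safe_log(self.alpha),
            safe_log(self.beta),
            safe_log(1.0 - self.beta),
        )


def single_obs_loglik(d: int, delta: int, E: ErrorModel) -> float:
    """Log-probability of one observed call given the predicted genotype.

    ``d`` is the observation (0, 1, or NA = -1); ``delta`` the genotype the
    tree predicts.  NA is the certain event and scores 0.
    """
    if d == NA:
        return 0.0
    if delta not in (0, 1) or d not in (0, 1):
        raise ValueError(f"invalid observation/genotype pair ({d}, {delta})")
    if delta == 0:
        p = E.alpha if d == 1 else 1.0 - E.alpha
    else:
        p = 1.0 - E.beta if d == 1 else E.beta
    return math.log(p) if p > 0.0 else -math.inf


class TreeScorer:
    """Scores trees over a fixed data set and error model.

    Precomputes the 0/1 indicator matrices of the observations so that the
    per-site, per-origin log-likelihood table of any tree reduces to two
    matrix products; ``score_batch`` stacks many candidate trees into one
    product, which is what makes the neighborhood sweeps of the search cheap.
    """

    def __init__(self, D: GenotypeMatrix, E: ErrorModel):
        self.D = D
        self.E = E
        self.M0 = (D.values == 0).astype(np.float64)  # (n, m)
        self.M1 = (D.values == 1).astype(np.float64)
        self.log_1ma, self.log_a, self.log_b, self.log_1mb = E.log_terms()
        # single-precision copies for the high-volume batched search path;
        # candidate ranking tolerates ~1e-4 absolute score error, and the
        # search recomputes its final answer in double precision
        self._M0_32 = self.M0.astype(np.float32)
        self._M1_32 = self.M1.astype(np.float32)
        self._has_log_zero = self.log_1ma <= _LOG_ZERO or self.log_a <= _LOG_ZERO \
            or self.log_b <= _LOG_ZERO or self.log_1mb <= _LOG_ZERO
        # decomposition used by the fused neighborhood kernel: S[c] =
        # base_site + sum of R rows over cells predicted mutated under c
        self._R = (
            self._M0_32 * np.float32(self.log_b - self.log_1ma)
            + self._M1_32 * np.float32(self.log_1mb - self.log_a)
        )
        self._base_site = (
            self._M0_32 * np.float32(self.log_1ma)
            + self._M1_32 * np.float32(self.log_a)
        ).sum(axis=0, dtype=np.float32)

    def _check(self, T: ClonalTree) -> None:
        if T.cells != self.D.cells:
            raise ValueError("tree and genotype matrix disagree on the cell set")

    def _delta(self, T: ClonalTree) -> np.ndarray:
        """(N-1, n) predicted genotypes: row c-2 is the pattern of origin c."""
        A = ancestry(T)
        return A[2:, T.assignment]

    def _weights(self, delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w0 = np.where(delta, self.log_b, self.log_1ma)
        w1 = np.where(delta, self.log_1mb, self.log_a)
        return w0, w1

    def site_clone_loglik(self, T: ClonalTree) -> np.ndarray:
        """``m x (N-1)`` table S with S[l, c-2] = sum_k log P(d_kl | origin c)."""
        self._check(T)
        w0, w1 = self._weights(self._delta(T))
        S = w0 @ self.M0 + w1 @ self.M1  # (N-1, m)
        S[S < _LOG_ZERO / 2] = -np.inf
        return S.T

    def marginal_loglik(self, T: ClonalTree) -> float:
        """Log P(D | T): origins marginalized uniformly over non-root clones."""
        self._check(T)
        if T.n_clones < 2:
            raise ValueError("likelihood needs at least one non-root clone")
        S = self.site_clone_loglik(T)
        per_site = _logsumexp(S, axis=1)
        return float(per_site.sum() - self.D.n_sites * math.log(T.n_clones - 1))

    def _score_deltas(self, deltas: np.ndarray, N: int, exact: bool = True) -> np.ndarray:
        """Scores from stacked predicted-genotype blocks, shape (B*(N-1), n)."""
        if exact:
            M0, M1, dtype = self.M0, self.M1, np.float64
        else:
            M0, M1, dtype = self._M0_32, self._M1_32, np.float32
        w0 = np.where(deltas, dtype(self.log_b), dtype(self.log_1ma))
        w1 = np.where(deltas, dtype(self.log_1mb), dtype(self.log_a))
        S = w0 @ M0 + w1 @ M1
        if self._has_log_zero:
            S[S < _LOG_ZERO / 2] = -np.inf
        S = S.reshape(-1, N - 1, self.D.n_sites)
        per_site = _logsumexp(S, axis=1)  # (B, m)
        return per_site.sum(axis=1, dtype=np.float64) - self.D.n_sites * math.log(N - 1)

    def score_batch(self, trees: list[ClonalTree], exact: bool = True) -> np.ndarray:
        """Marginal log-likelihoods of many same-size trees in one product."""
        if not trees:
            return np.zeros(0)
        N = trees[0].n_clones
        if any(t.n_clones != N for t in trees):
            # mixed sizes: fall back to per-tree scoring
            return np.array([self.marginal_loglik(t) for t in trees])
        deltas = np.concatenate([self._delta(t) for t in trees])  # (B*(N-1), n)
        return self._score_deltas(deltas, N, exact=exact)

    def score_neighborhood(
        self,
        T: ClonalTree,
        moves: list[tuple[int, int]],
        A: np.ndarray | None = None,
        exact: bool = False,
    ) -> np.ndarray:
        """Scores of prune-and-regraft neighbors given as ``(v, t)`` moves.

        Updates the ancestry of ``T`` incrementally per move — reattaching
        the subtree of ``v`` below ``t`` only changes the descendant sets of
        the old and new ancestors of ``v`` — which makes the full
        neighborhood sweep of the search cheap.
        """
        self._check(T)
        if not moves:
            return np.zeros(0)
        N, n = T.n_clones, T.n_cells
        if not exact:
            R_clone = np.zeros((N + 1, self.D.n_sites), dtype=np.float32)
            np.add.at(R_clone, T.assignment, self._R)
            moves_arr = np.asarray(moves, dtype=np.int64)
            log_norm = self.D.n_sites * math.log(N - 1)
            kernel = _score_moves_kernel_nb if _HAVE_NUMBA else _score_moves_kernel_py
            return kernel(
                T.parent.copy(), moves_arr, R_clone, self._base_site, log_norm
            )
        if A is None:
            A = ancestry(T)
        asg = T.assignment
        deltas = np.empty((len(moves), N - 1, n), dtype=bool)
        for i, (v, t) in enumerate(moves):
            Av = A.copy()
            sub = A[v]
            old_anc = np.flatnonzero(A[:, v])
            Av[old_anc[old_anc != v]] &= ~sub
            Av[np.flatnonzero(A[:, t])] |= sub
            deltas[i] = Av[2:, asg]
        return self._score_deltas(deltas.reshape(-1, n), N, exact=exact)


def site_clone_loglik(D: GenotypeMatrix, T: ClonalTree, E: ErrorModel) -> np.ndarray:
    """``m x (N-1)`` per-site, per-origin log-likelihood table for tree ``T``."""
    return TreeScorer(D, E).site_clone_loglik(T)


def marginal_loglik(D: GenotypeMatrix, T: ClonalTree, E: ErrorModel) -> float:
    """Marginal log-likelihood log P(D | T) of a clonal lineage tree."""
    return TreeScorer(D, E).marginal_loglik(T)


def known_theta_loglik(
    D: GenotypeMatrix, T: ClonalTree, theta: dict[str, int], E: ErrorModel
) -> float:
    """Log-likelihood with known mutation origins: sum_l S[l, theta_l].

    ``theta`` maps each site identifier to the clone where the mutation
    originated; origins must be non-root clones.
    """
    S = site_clone_loglik(D, T, E)
    total = 0.0
    for l, site in enumerate(D.sites):
        c = theta[site]
        if not 2 <= c <= T.n_clones:
            raise ValueError(
                f"origin of site {site!r} must be a non-root clone, got {c}"
            )
        total += S[l, c - 2]
    return float(total)
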