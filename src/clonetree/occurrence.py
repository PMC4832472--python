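"""Posterior placement of mutations on a tree and expected branch lengths.

Given the final tree, each mutation site gets a posterior distribution over
the clone in which it originated (uniform prior over non-root clones, so the
posterior is just the row-normalized per-site likelihood table).  Summing a
clone's posterior mass over sites gives the expected number of mutations on
the edge entering that clone, which serves as a branch length: the total
over all edges is exactly the number of sites.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .genotype_io import GenotypeMatrix
from .likelihood import ErrorModel, site_clone_loglik
from .tree import ClonalTree

__all__ = ["posterior_theta", "branch_lengths", "map_theta", "write_posterior", "write_branch_lengths"]


def posterior_theta(D: GenotypeMatrix, T: ClonalTree, E: ErrorModel) -> pd.DataFrame:
    """``m x (N-1)`` posterior P(origin of site l = clone c | T, D).

    Rows are sites, columns non-root clones 2..N; each row sums to one.
    A site with no observed calls has a flat likelihood and therefore a
    uniform posterior.
    """
    S = site_clone_loglik(D, T, E)
    P = np.exp(S - logsumexp(S, axis=1, keepdims=True))
    return pd.DataFrame(P, index=list(D.sites), columns=list(range(2, T.n_clones + 1)))


def branch_lengths(P: pd.DataFrame, T: ClonalTree) -> dict[tuple[int, int], float]:
    """Expected mutation count per edge: column sums of the posterior.

    Keys are ``(parent, child)`` clone pairs; values sum to the number of
    sites, since every mutation occurs exactly once in expectation.
    """
    sums = P.sum(axis=0)
    return {
        (int(T.parent[c]), c): float(sums[c]) for c in range(2, T.n_clones + 1)
    }


def map_theta(P: pd.DataFrame) -> tuple[dict[str, int], dict[str, bool]]:
    """Maximum a posteriori origin clone per site.

    Returns the site-to-clone map and a per-site tie flag; ties resolve to
    the lowest clone index.
    """
    arr = P.to_numpy()
    best = arr.argmax(axis=1)
    ties = (np.isclose(arr, arr[np.arange(len(arr)), best][:, None])).sum(axis=1) > 1
    clones = list(P.columns)
    assignment = {site: int(clones[i]) for site, i in zip(P.index, best)}
    tie_flag = {site: bool(t) for site, t in zip(P.index, ties)}
    return assignment, tie_flag


def write_posterior(P: pd.DataFrame, path: str | Path) -> None:
    """Sites-by-clones posterior table as TSV (columns ``clone<i>``)."""
    out = P.copy()
    out.columns = [f"clone{c}" for c in P.columns]
    out.index.name = "site"
    out.to_csv(path, sep="\t")


def write_branch_lengths(L: dict[tuple[int, int], float], path: str | Path) -> None:
    """Edge list with expected mutation counts as TSV."""
    rows = [f"{p}\t{c}\t{length:.10g}" for (p, c), length in sorted(L.items())]
    Path(path).write_text("parent\tchild\texpected_mutations\n" + "\n".join(rows) + "\n")
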