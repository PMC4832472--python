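"""Grid maximum-likelihood estimation of the genotyping error rates.

The false positive and false negative rates of the binarized call matrix
are not the raw sequencing FDR and allele-dropout rates: site selection,
census filtering and binarization all reshape them, so they are treated as
free model parameters and estimated from the data.  For every (alpha, beta)
combination on a grid, the full three-step tree inference is run and the
pair whose best tree has the highest marginal log-likelihood wins.  The
likelihood surface is flat around the optimum, so a coarse grid suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .likelihood import ErrorModel
from .search import InferenceResult, SearchConfig, infer

__all__ = ["ParameterGrid", "default_grid", "estimate_parameters"]


@dataclass(frozen=True)
class ParameterGrid:
    """Candidate false positive rates and false negative rates."""

    alphas: tuple[float, ...]
    betas: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, vals in (("alphas", self.alphas), ("betas", self.betas)):
            vals = tuple(float(v) for v in vals)
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"{name} must be distinct")
            if any(not 0.0 <= v < 1.0 for v in vals):
                raise ValueError(f"{name} must lie in [0, 1)")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be increasing")


def default_grid() -> ParameterGrid:
    """Coarse default grid: 0.01 and 0.05..0.45 in steps of 0.05, both axes."""
    values = (0.01, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)
    return ParameterGrid(values, values)


def estimate_parameters(
    D: GenotypeMatrix,
    grid: ParameterGrid | None = None,
    cfg: SearchConfig | None = None,
) -> tuple[ErrorModel, InferenceResult, pd.DataFrame]:
    """Pick the error rates whose inferred tree scores highest.

    Runs the full three-step inference once per grid cell (same search
    configuration everywhere, so cells are comparable) and returns the
    winning error model, its inference result, and the alphas-by-betas
    log-likelihood surface.  Ties resolve to the earlier grid cell in
    row-major (alpha, beta) order.
    """
    grid = grid or default_grid()
    cfg = cfg or SearchConfig()
    surface = np.full((len(grid.alphas), len(grid.betas)), -np.inf)
    best: tuple[ErrorModel, InferenceResult] | None = None
    for i, alpha in enumerate(grid.alphas):
        for j, beta in enumerate(grid.betas):
            E = ErrorModel(alpha, beta)
            res = infer(D, E, cfg)
            surface[i, j] = res.loglik
            if best is None or res.loglik > best[1].loglik:
                best = (E, res)
    assert best is not None
    frame = pd.DataFrame(surface, index=list(grid.alphas), columns=list(grid.betas))
    frame.index.name = "alpha"
    frame.columns.name = "beta"
    return best[0], best[1], frame
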