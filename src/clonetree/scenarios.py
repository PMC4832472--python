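"""Deterministic benchmark scenarios for the simulation studies.

One default setting — ten clones, none unobserved, 20 cells, 200 sites,
false positive rate 0.2, false negative rate 0.1, 20% missing — plus
one-factor-at-a-time variants along each simulation axis, five fixed-seed
replicates each.  These are the conditions under which the method's
robustness (parameter recovery, stability of the clone count in the Bayes
factor threshold) is evaluated; regenerating a scenario from its recorded
seeds is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

from .genotype_io import write_genotypes
from .simulate import SimulationConfig, simulate_dataset
from .tree import write_edge_list

__all__ = ["ScenarioSpec", "DEFAULT_CONFIG", "build_scenarios", "materialize"]

DEFAULT_CONFIG = SimulationConfig(
    n_clones=10, n_unobserved=0, n_cells=20, n_sites=200,
    alpha=0.2, beta=0.1, p_missing=0.2,
)

N_REPLICATES = 5

# one-factor-at-a-time variation axes; levels approximate the usual
# benchmark ranges for single-cell SNV data sets
_AXES: dict[str, tuple] = {
    "n_cells": (10, 50),
    "n_sites": (50, 500),
    "n_clones": (1, 5, 15),
    "n_unobserved": (1, 2),
    "alpha": (0.05, 0.4),
    "beta": (0.05, 0.2),
    "p_missing": (0.0, 0.4),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """A named simulation setting with fixed replicate seeds."""

    name: str
    config: SimulationConfig
    seeds: tuple[int, ...]


def _seeds_for(index: int) -> tuple[int, ...]:
    base = 10_000 + 100 * index
    return tuple(base + r for r in range(N_REPLICATES))


def build_scenarios() -> list[ScenarioSpec]:
    """Default scenario plus one-factor-at-a-time variants, 5 replicates each."""
    scenarios = [ScenarioSpec("default", DEFAULT_CONFIG, _seeds_for(0))]
    index = 1
    for axis, levels in _AXES.items():
        for level in levels:
            cfg = replace(DEFAULT_CONFIG, **{axis: level})
            if cfg.n_cells < cfg.n_clones - cfg.n_unobserved:
                cfg = replace(cfg, n_cells=cfg.n_clones - cfg.n_unobserved)
            if cfg.n_unobserved >= cfg.n_clones:
                continue
            scenarios.append(
                ScenarioSpec(f"{axis}={level}", cfg, _seeds_for(index))
            )
            index += 1
    return scenarios


def materialize(spec: ScenarioSpec, outdir: str | Path) -> list[Path]:
    """Write every replicate of a scenario to ``outdir/<name>/<replicate>/``.

    Each replicate directory holds ``genotypes.tsv``, ``truth_tree.tsv``,
    ``theta.tsv`` and ``meta.json`` (the config and seed used).
    """
    outdir = Path(outdir)
    written = []
    for r, seed in enumerate(spec.seeds, start=1):
        cfg = replace(spec.config, seed=seed)
        D, truth = simulate_dataset(cfg)
        rep_dir = outdir / spec.name / f"rep{r}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        write_genotypes(D, rep_dir / "genotypes.tsv")
        write_edge_list(truth.tree, rep_dir / "truth_tree.tsv")
        theta_lines = ["site\tclone"] + [
            f"{site}\t{clone}" for site, clone in truth.theta.items()
        ]
        (rep_dir / "theta.tsv").write_text("\n".join(theta_lines) + "\n")
        (rep_dir / "meta.json").write_text(
            json.dumps({"scenario": spec.name, "seed": seed, **cfg.__dict__}, indent=2)
            + "\n"
        )
        written.append(rep_dir)
    return written
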