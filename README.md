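# clonetree

Clonal lineage tree inference from noisy single-cell SNV genotype matrices.

## The problem

Single-cell sequencing of a tumor yields, after variant calling and
binarization, a matrix `D = (d_kl)` of mutation calls — cell `k` is 0
(unmutated), 1 (mutated) or NA (no call) at somatic variant site `l`.
These matrices are noisy: allele dropout makes false negative rates of
~0.1–0.4 routine, census filtering leaves recurrent false positives, and
large fractions of entries are missing entirely.  On top of that, the
sampled cells usually represent only part of the tumor — whole ancestral
subpopulations can be unobserved.

`clonetree` reconstructs the tumor's clonal substructure from such a
matrix: it clusters cells into clones, infers the rooted lineage tree of
those clones (root = the unmutated normal), detects unobserved ancestral
clones where the mutation patterns demand them, places each mutation on
the tree, and estimates the error rates of the matrix itself.  It is aimed
at tumor-evolution studies working with tens of cells and hundreds of
somatic SNVs.

## The model in brief

Under the infinite-sites assumption, a mutation originating in clone `c`
is present in `c` and all of its descendants.  Each observed call is a
noisy draw of the predicted genotype with global false positive rate α and
false negative rate β; NA contributes probability one.  With a uniform
prior for each mutation's origin clone `θ_l ∈ {2..N}`, the tree likelihood
marginalizes the origins:

    P(D | T) = (N−1)^(−m) · Π_l Σ_{c=2}^{N} Π_k P(d_kl | δ_kl(T, c))

Inference is a three-step heuristic: (1) best-first prune-and-regraft
search over cell lineage trees from a star start; (2) insertion of
unobserved clones at branch points, each accepted only if the Bayes factor
against the smaller model exceeds ε (default 10); (3) clustering of cells
by merging clones along edges while the likelihood stays within 1/ε of the
best solution.  Unknown α, β are estimated by running the full inference
over a coarse grid and keeping the maximum-likelihood cell.  Details and
design rationale: [docs/methods.md](docs/methods.md).

## Worked example

```bash
# simulate a tumor: 5 clones, 10 cells, 200 sites, 1% error rates, 20% missing
clonetree simulate --clones 5 --cells 10 --sites 200 \
    --fpr 0.01 --fnr 0.01 --missing 0.2 --seed 3 -o sim/

# infer the clonal tree at known error rates
clonetree infer sim/genotypes.tsv --fpr 0.01 --fnr 0.01 --seed 3 -o out/

# compare against the simulated ground truth
clonetree compare --truth-tree sim/truth_tree.tsv --pred-tree out/tree.tsv --normalized
```

The infer step prints

    inferred 6 clones (loglik -406.83, alpha=0.01, beta=0.01); outputs in out

meaning the final model has 6 clones including the cell-free root (so 5
tumor clones, matching the simulation) and a marginal log-likelihood of
−406.83 under the 1% error model.  The compare step prints

    measure	value
    shortest_path_distance	0
    v_measure	1

a normalized pairwise cell shortest-path distance of 0 and a V-measure of
1: the reconstruction is exact — every cell is in the right clone and the
clone tree has the right shape.  `out/` also holds the tree as an edge
list, Newick (branch lengths = expected mutations per edge) and DOT, the
per-site posterior over origin clones (`theta_posterior.tsv`), and a JSON
run report.  Omitting `--fpr/--fnr` makes `infer` estimate both rates
first by grid maximum likelihood (≈ 100 full inference runs; minutes at
this size, use `clonetree estimate` to get the likelihood surface).

The same pipeline is available as a library:

```python
import clonetree as ct

cfg = ct.SimulationConfig(n_clones=5, n_cells=10, n_sites=200,
                          alpha=0.01, beta=0.01, p_missing=0.2, seed=3)
D, truth = ct.simulate_dataset(cfg)
res = ct.infer(D, ct.ErrorModel(0.01, 0.01))
print(res.tree.n_clones, res.loglik)          # 6 -406.83...
print(ct.shortest_path_distance(res.tree, truth.tree))  # 0.0
```

## Applying it to real data

Real matrices (e.g. the published 44-cell bladder-cancer and 58-cell
thrombocythemia data sets) are TSV/CSV files with sites as rows and cells
as columns; `clonetree infer <matrix>` without `--fpr/--fnr` reproduces
the published analyses' estimation-then-inference pipeline.  Budget hours
for the full default grid at that size, and blacklist LOH-affected regions
beforehand — mutation loss violates the model's assumptions.
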