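# Methods

`clonetree` reconstructs the clonal substructure of a tumor from binary
somatic-SNV calls of single cells.  This note documents the model, the
inference procedure, the simulator, the evaluation measures, and the
numerical and design choices a maintainer should know about.

## Model

**Data.** An `n × m` matrix `D = (d_kl)` of observed genotypes: cell `k`,
variant site `l`, values 0 (unmutated), 1 (mutated) or NA (no call).  The
input is assumed to be pre-filtered to somatic variant sites; variant
calling, census filtering and binarization happen upstream.

**Clonal lineage tree.** A rooted directed tree `T` over clones `1..N`,
root = clone 1 = the unmutated normal, which never holds cells.  Each cell
belongs to exactly one non-root clone; non-root clones without cells are
*unobserved* (latent) clones.  Under the infinite-sites assumption (each
site mutates once, mutations are never lost) a mutation originating in
clone `c` is present in `c` and all its descendants and absent elsewhere,
so ancestral mutation sets are nested within descendants'.

**Observation model.** Each call is an independent draw of the predicted
genotype `δ_kl` with global false positive rate `α = P(1 | δ=0)` and false
negative rate `β = P(0 | δ=1)`; NA is the certain event `{0,1}` with
probability 1.  `α` and `β` are rates of the *binarized call matrix*, not
the raw sequencing FDR or allele-dropout rate — upstream site selection,
census filtering and binarization reshape those substantially, which is why
the rates are estimated from the matrix itself (below).

**Marginal likelihood.** The origin `θ_l` of each mutation is unknown and
carries a uniform prior over the `N−1` non-root clones.  Marginalizing,

```
log P(D|T) = Σ_l logsumexp_{c=2..N} S[l,c]  −  m·log(N−1),
S[l,c] = Σ_k log P(d_kl | δ = [c ancestor-or-self of clone(k)])
```

All arithmetic is in log space.  `S` rows of an all-NA site are zero
(likelihood 1 everywhere), so such sites are accepted with a warning rather
than rejected.  Unobserved clones are legal `θ` values and enter the
`N−1` normalization, following the formula literally.  The model prior over
trees is uniform, so posterior comparison reduces to likelihood comparison
and Bayes factors to log-likelihood differences.

## Inference

Three stages, composed by `infer`:

1. **Initial search** over *cell* lineage trees (every cell its own clone,
   no latent clones), starting from the star tree.  The local move is
   single-subtree prune-and-regraft: detach a non-root clone with its
   subtree and reattach it below any clone outside that subtree.  This move
   set is symmetric, gives the star tree `n(n−1)` neighbors, and reaches the
   entire `(n+1)^(n−1)`-tree space (verified by exhaustive BFS on small
   `n`).  The search is a deterministic best-first expansion: repeatedly
   expand the highest-scoring solution whose neighborhood is not yet fully
   scored — steepest ascent while improving, automatic backtracking to the
   best previous solution on a stall.  It terminates when no expansion has
   improved the incumbent for `max_stall × backtrack_pool` rounds (default
   5 × 10 = 50), when the frontier empties (small spaces end up searched
   exhaustively), or at the `max_iter` cap on scored trees (default 2·10⁵,
   logged when hit).  Ties break towards the earliest generated move, so
   reruns are bit-identical.

2. **Unobserved-clone testing.**  For each branch point (clone with ≥ 2
   children) a latent clone is inserted that adopts all of the branch
   point's children; its position and child set are then optimized by the
   same best-first search restricted to moves that involve the latent node
   (as the moved node, the move target, or the parent of the moved node).
   The restricted subproblem has an O(N) move space and uses a reduced
   patience of `3 × max_stall`.  A strict steepest ascent is *not* enough
   here: the correct placement can require passing through lower-likelihood
   intermediate trees (demonstrated by a 4-cell branching example in the
   test suite).  The best enlarged model is accepted iff its log-likelihood
   gain exceeds `log ε`; accepted expansions repeat with `N+1` clones.

3. **Cell clustering.**  Candidate moves are child-into-parent merges along
   tree edges (never into the root).  The best merge is applied as long as
   the resulting log-likelihood stays above the best clustering solution
   seen so far minus `log ε`; afterwards latent clones left with fewer than
   two children are spliced out, since linearly-connecting unobserved
   clones are unidentifiable.  Sibling–sibling merges are not considered
   directly; a sibling pair can merge through a shared parent in two steps.

**Bayes factor threshold ε** (default 10, "strong evidence" on Jeffreys's
scale) guards both model expansion and clustering; the two uses share one
knob.  The final result's log-likelihood is always recomputed from scratch
on the final tree.

## Error-rate estimation

`estimate_parameters` runs the full three-step inference for every `(α, β)`
combination of a grid and returns the pair whose best tree scores highest
(maximum likelihood over a grid; no penalty term — all cells share the same
data and model space).  The default grid is `{0.01, 0.05, 0.10, …, 0.45}`
on both axes; the surface around the optimum is flat, so a coarse grid
suffices and the exact spacing is a pragmatic choice.  Cells are evaluated
sequentially in row-major order and ties resolve to the earlier cell, so
the result is deterministic and identical to any parallel schedule.

## Simulator

Matches the benchmark generator for this class of method:

* **Trees:** clone 2 attaches to the root; subsequent clones attach to a
  uniformly random existing non-root clone.  If `n_unobserved > 0`, trees
  are redrawn (up to 10⁵ attempts) until at least that many non-root branch
  points exist; the unobserved clones are drawn uniformly among them.  The
  root itself is never selected — it is already cell-free, and flagging it
  would silently reduce the effective clone number.  Every observed clone
  receives one cell; remaining cells join observed clones with probability
  proportional to current size (preferential attachment → skewed clone
  sizes).
* **Genotypes:** per-site origins uniform over non-root clones (latent
  clones included), true genotypes from ancestry.  Noise, in order, on
  disjoint entry sets: a fraction `p_missing` of all entries becomes NA;
  a fraction `α` of truly-unmutated non-missing entries flips to 1; a
  fraction `β` of truly-mutated non-missing entries flips to 0.  Fractions
  are exact counts (`round(f · eligible)`), not i.i.d. coin flips, so small
  matrices hit the nominal rates; this makes, e.g., the default setting
  mask exactly 800 of 4 000 entries.  Sites left with no observed mutant
  call receive one rescue false positive in a random cell (preferring cells
  with a non-missing entry at the site) — variant calling would never
  report such a site.  Finally the cell order is shuffled; identifiers
  travel with rows, so ground truth stays linked by cell id.

Defaults are the standard benchmark conditions: 10 clones, none unobserved,
20 cells, 200 sites, `α = 0.2`, `β = 0.1`, 20% missing.  What the simulator
does **not** emulate: doublets, site-specific or cell-specific error rates,
copy-number events and LOH (which can delete true mutations and violate the
infinite-sites assumption), and correlated missingness (amplification
failures cluster by cell and by locus in real data).  Passing round-trip
tests therefore demonstrates correctness of the inference under its own
generative model, not robustness to these real-data artifacts.

## Evaluation measures

* **V-measure** (harmonic mean of homogeneity and completeness of the cell
  partition), computed via scikit-learn and cross-checked against a direct
  entropy computation in the tests.
* **Pairwise cell shortest-path distance:** both trees get one synthetic
  cell anchored in the root; for every unordered cell pair the edge
  distance between their clones (0 if co-clustered) is tabulated, and the
  absolute differences are summed.  The optional normalization divides by
  the number of pairs actually summed, `(n+1)n/2` including the root cell —
  a deliberate choice where only the unnormalized sum is well established;
  distances of 0 are unaffected.
* **Mutation order accuracy:** over site pairs whose true origins are
  different clones, the average of (i) the fraction of truly
  ancestor-ordered pairs whose order is reproduced and (ii) the fraction of
  truly mutually-exclusive (separate-branch) pairs recovered as exclusive.
  Undefined (NaN) when the truth has no mutually exclusive pair, e.g. for a
  linear tree.  If the truth has exclusive pairs but no ordered ones,
  component (ii) alone is returned.

## Numerical choices

* Log-space throughout, with a numerically safe log-sum-exp; `α = 0` or
  `β = 0` are legal — log 0 is carried as a finite sentinel (−10³⁰) through
  the matrix products (avoiding `0 × −inf = NaN`) and restored to −inf
  afterwards.
* The search ranks candidates in single precision — an inner kernel
  maintains the per-origin score table as subtree sums of per-clone
  adjustment rows, updated incrementally per move (only the old and new
  ancestor chains of the moved subtree change).  The winner of each search
  is re-scored in double precision, and the public likelihood functions are
  double-precision end to end (validated against a brute-force origin
  enumeration to 1e-12).  Trees whose scores differ by less than ~1e-6 are
  effectively tied for the search; noise-free test scenarios therefore use
  error rates of 1e-3 rather than arbitrarily tiny values, keeping genuine
  model distinctions far above ranking resolution.
* Tie-breaks are deterministic everywhere (earliest generated move; lowest
  clone index for MAP origins, with a tie flag).
* Clone labels are kept dense (`1..N`, root fixed at 1) after merges and
  pruning; edit operations return the old-to-new label map.

## Problem sizes used in the test suite

Unit tests run on instances of up to ~10 cells within seconds.  The
acceptance checks use the benchmark conditions themselves: likelihood
equivalence on 200 random small instances; exhaustive-enumeration search
checks on 4 cells × 100 replicates; grid-ML error-rate recovery on five
simulated data sets of 20 cells × 200 sites (the dominant cost — a full
three-step inference per grid cell, 100 cells per data set); a 20-seed
low-noise round trip at 10 cells × 200 sites; and ε-stability on the five
default-scenario replicates, reusing the ε-independent initial search per
replicate.

## Known limitations

* The search is heuristic; on noisy data the three-stage pipeline can
  settle below the best achievable clonal tree (the staging itself — cell
  tree first, latent clones second, clustering third — creates path
  dependence).  Exhaustive search is only feasible to ~9 tree nodes.
* The inferred number of clones is *not* perfectly constant in ε across
  simulated replicates: merges and expansions whose likelihood margins fall
  between `log 5` and `log 1000` occur in the default noisy setting (a real
  single-cell clone can cost < 7 log-units to absorb when 20% of entries
  are missing and α = 0.2), so the clone count may move by 1–3 over that ε
  range while the V-measure stays high.  Stability holds in the sense of
  "largely independent", not exact invariance; ε = 10 sits in the flattest
  part of the range.
* Copy-number variation, LOH and doublets are out of scope; LOH-affected
  regions should be blacklisted upstream.
* Error rates are global; per-cell or per-site rates are not modeled.
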