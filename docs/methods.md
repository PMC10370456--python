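# Methods

`phylorepro` is a self-contained, desk-scale laboratory for studying the
*computational reproducibility* of maximum-likelihood (ML) phylogenies: the
phenomenon that two runs of the same tree-search program, on identical data
and settings, differing only in random seed, can return different
topologies.  The package contains its own simulation engine, its own
likelihood/search engine, and the analysis protocols that relate
irreproducibility to inaccuracy and to the information content of the data.

## The model and its core quantities

Sequences evolve along an unrooted binary tree under a reversible nucleotide
substitution model (HKY or GTR), optionally with discrete-gamma rate
heterogeneity across sites ("+G4": four equal-probability categories whose
rates are the means of the quantile bins of a mean-one gamma distribution).
Branch lengths are expected substitutions per site; the generator matrix is
normalized to unit mean rate.

* **Log-likelihood.** Felsenstein pruning over compressed site patterns,
  averaged over gamma categories with equal weights, in natural-log units.
  Conditional-likelihood vectors are rescaled per pattern at every internal
  node, with accumulated log scalers, so deep trees and long alignments do
  not underflow.
* **Topological distance.** Robinson–Foulds (RF) distance on non-trivial
  unrooted bipartitions; percent difference `d_RF / (2(m−3)) × 100` for
  fully resolved trees on `m` taxa.  Trees are compared as unrooted objects
  throughout; rooted Newick input is unrooted on parse (degree-2 root
  suppressed, edge lengths summed).
* **Phylogenetic information.** The expected substitution count of a data
  set: (sum of true-tree branch lengths) × (alignment length).
* **Computational irreproducibility.** Two searches with seeds 111 and 123
  (the package defaults) returning topologically distinct best trees.
  Branch lengths are ignored in this judgement.
* **Optimality forest.** For one alignment, the set of distinct topologies
  whose optimized log-likelihood strictly exceeds the optimized true-tree
  log-likelihood.  Its *breadth* is the log-likelihood gap between the best
  tree found and the true tree; an empty forest has no breadth (reported
  absent per data set, 0 in level means so aggregates stay defined).

## The search engine

The heuristic search is intentionally an independent, minimal ML engine —
multi-start greedy hill climbing — because the object of study is the
*mechanism* of seed dependence, not any particular program's heuristics:

1. **Starting trees** alternate stepwise-addition trees under seeded random
   taxon orders with neighbor-joining trees built from bootstrap-resampled
   site columns (JC distances, scikit-bio's NJ).
2. **Hill climbing** screens every NNI rearrangement using cached
   directional partials, re-optimizing only the central edge of each
   candidate (the screened score is a lower bound of the candidate's fully
   optimized log-likelihood).  Candidates are ranked under a seed-shuffled
   order; the top `refine_k` (default 3) are fully branch-length-optimized,
   and the first that improves the current log-likelihood by more than
   `epsilon` is accepted.  SPR moves are available by configuration but off
   by default; at desk scale NNI suffices to generate every phenomenon the
   package studies.
3. **Branch-length optimization** is round-robin single-edge Brent
   maximization.  Each sweep is one exact sequential traversal with
   incrementally updated partials, and along a single edge the site
   likelihood is evaluated in spectral form
   (`site(t) = Σ_a c_a e^{λ_a r t}`), so per-edge scans are cheap.  Sweeps
   stop when a full sweep gains less than `epsilon`; the sweep trace is
   monotone non-decreasing by construction.
4. **Determinism.** The seed fully determines starting trees and
   tie-breaking; identical inputs and seed give byte-identical results
   across process invocations.  An exhaustive oracle (all `(2m−5)!!`
   topologies, m ≤ 8) provides the seed-free global optimum for validation.

Key numerical parameters (all exposed in `SearchConfig` /
`TreeLikelihood`): log-likelihood epsilon `1e-4` (both the move-acceptance
threshold and the branch-optimization convergence tolerance), per-branch
Brent tolerance `1e-6`, branch-length bounds `[1e-8, 10]`, sweep cap 60.
Because independently optimized trees resolve their log-likelihoods only to
`epsilon`, all superiority comparisons between trees (inferred vs true,
exhaustive vs heuristic) treat differences below `1e-4` as ties.

## The synthetic-data generator

The generator is the package's replacement for large published simulation
collections; it reproduces their statistical structure at taxon counts
where thousands of ML searches finish in minutes on one CPU.

* **Topologies** are Yule (pure-birth) trees, freshly drawn per data set
  (default 16 taxa), rather than one fixed large empirical topology.
  Taxon counts up to 8 are reserved for exhaustive oracles.
* **Hundred-like collection** (default 100 data sets): HKY, sequence
  lengths 258–2,000 sites, GC content 39–82% (frequencies
  `((1−GC)/2, GC/2, GC/2, (1−GC)/2)`), transition/transversion ratio
  1.35–2.6, autocorrelated lognormal lineage rates (Kishino–Thorne
  recursion; variance 0.04 per unit time of the height-normalized time
  tree, initial rate 2×10⁻⁹ subs/site/year — both configurable, as the
  hyperparameters are not derivable from first principles).  Total tree
  length is drawn uniformly from 0.05–0.3 expected substitutions/site, so
  information spans roughly 15–600 expected substitutions — matching the
  span (tens to hundreds of informative sites) over which irreproducibility
  transitions from common to rare.
* **Informativeness ladder** (default 3 levels × 15 data sets, 16 taxa):
  GTR+G4 with gamma shape 1.0, 300–1,000 sites, target expected-substitution
  counts spaced geometrically from 100 to 600, realized by scaling the true
  tree's total length per data set.  The bounds keep the ladder away from
  the two degenerate extremes: below ~100 substitutions the likelihood
  surface is nearly flat in topology, while far above ~600 at these
  alignment lengths per-site tree lengths exceed ≈2 and multiple hits
  (saturation) erode signal even as the nominal substitution count grows.
  The geometric spacing of levels is this package's choice of ladder.
* Per-site gamma categories are fixed at simulation time; alignments are
  gap-free (no indel process).  Every data set carries a derived seed
  (counter-based `SeedSequence` spawning) so it can be regenerated alone.

**What the generator does not emulate:** model misspecification (inference
uses the generating model family), alignment error, indels, selection or
compositional heterogeneity across lineages, and linked-gene effects.
Passing tests therefore demonstrate the *mechanistic* claims — that seed
dependence arises from multiple near-optimal topologies on low-information
data, and disappears in the information limit — not numerical rates for any
empirical collection.

## Analysis protocols

* **Two-run protocol**: two searches differing only in seed (111/123; equal
  seeds are refused since they mandatorily reproduce), plus the true tree
  re-optimized on the data; records percent RF distances among
  {Q1, Q2, T} and all pairwise log-likelihood differences.
* **Q3 protocol**: the search is seeded with the true topology (branch
  lengths optimized first), guaranteeing its neighborhood is explored; the
  remaining starts are generated exactly as in a normal run, so the Q3
  search effort contains a normal search's rather than replacing it.
* **Forest construction**: trace-retaining hill climbs from bootstrap /
  stepwise starts; all evaluated topologies (accepted and rejected) are
  pooled, deduplicated by canonical splits, re-optimized, and filtered by
  strict LL superiority over the true tree.  The ladder and consistency
  presets skip full re-optimization of pooled topologies whose quick score
  lies more than 5 log units below the true tree's (the quick score is a
  lower bound, so this can only drop far-from-membership candidates; the
  forest near the membership boundary is computed exactly).
* **Patterns**: P1 — among irreproducible data sets, mean ΔQ1Q2 < mean
  ΔQ1T (one-sided paired bootstrap); P2 — the two runs are equally
  inaccurate (overlapping 95% bootstrap CIs); P3 — inferred LL ≥ optimized
  true-tree LL in ≥90% of data sets; P4 — irreproducibility fraction
  non-increasing with information level.  Bootstrap CIs (2,000 resamples)
  replace exact percentage matching because an independent engine cannot
  reproduce another program's numeric frequencies; the claims under test
  are ordinal.

## Problem sizes

Default experiment sizes — 100 HKY data sets at 16 taxa, 45 GTR+G4 data
sets at 12 taxa across 3 information levels, 20 consistency replicates at 8
taxa × 50,000 sites, 50-seed oracle-recovery checks at 6 taxa — were chosen
so each study completes in minutes on a single CPU while keeping enough
replication for the bootstrap statistics to be stable.

## Known limitations

* **Forest breadth vs information at desk scale.**  Sweeping information by
  scaling tree length at a fixed site range reliably drives the
  *irreproducibility fraction* and (broadly) the inference error downward,
  but not the optimality-forest *breadth*: breadth accumulates over
  internal branches, and with ≤16 taxa (13 internal branches, vs 61 at the
  64-taxon scale this emulates) the finite-sample noise added by the longer
  branches a higher substitution target requires offsets the signal it
  adds.  In the package's ladder experiments the level means of breadth are
  not monotone decreasing.  The decline is recovered where consistency
  theory guarantees it — raising information through *sites* (the 50,000
  site consistency study collapses breadth to ~0) — so treat
  breadth-vs-information conclusions from tree-length-swept ladders at
  small taxon counts with caution.
* The engine's irreproducibility *rates* depend on its own search effort
  (`n_starts`, NNI-only moves) and will not numerically match any external
  program; only directions and orderings of effects are asserted.
* Coordinate-ascent branch optimization resolves log-likelihoods to the
  epsilon tolerance, not machine precision; all cross-tree LL comparisons
  honor that resolution.
* `estimate_model_params` optimizes kappa and gamma shape (with empirical
  base frequencies); GTR exchangeability estimation is not implemented —
  simulated data are scored under their generating model, and user data
  need an externally chosen model.
* Multifurcating trees are accepted by the RF machinery but not produced by
  the simulator or search; `rf_percent` requires full resolution since its
  normalization assumes binary trees.
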