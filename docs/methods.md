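# Methods

## Scope and data model

The package analyses the pan-genome of a small set of conspecific bacterial
genomes. Its central object is the boolean presence/absence matrix of gene
families × genomes; all downstream statistics are functions of that matrix.
Construction of the matrix (ortholog clustering) and its analysis
(partitioning, accumulation curves, model fits, annotation cross-tabs) are
deliberately decoupled: any stage can be fed precomputed tables instead.

## Ortholog clustering

**Similarity graph.** Imported all-vs-all hit tables use the common
12-column tabular dialect. Hits are filtered at an e-value cutoff
(default 1e-5), self-hits are discarded, and reciprocal hits collapse to one
undirected edge. The default edge weight is `-log10(evalue)` capped at 200
(monotone in significance and bounded, the customary ortholog-graph
transform); the raw bit score is available as an alternative. Proteins whose
hits are all filtered remain in the graph as isolated nodes, so they
correctly emerge as singleton families.

The built-in scorer exists to make the pipeline self-contained on sequence
input: candidate pairs must share at least one k-mer (k = 5), and candidates
are scored by global alignment with BLOSUM62 and affine gaps (open 11,
extend 1 — the common protein-search defaults), keeping pairs scoring at
least 50. It makes no attempt at e-value statistics; its scores are raw
alignment scores, and the 50-score default is a conservative screen for the
short synthetic proteins it is mostly used on.

**Markov clustering.** The flow matrix starts from the weighted adjacency
matrix with self-loops set to each node's maximum incident edge weight
(standard regularization that prevents flow oscillation), column-normalized.
Each iteration applies expansion (matrix power, default 2), inflation
(entrywise power, default 2.0, followed by column renormalization), and
pruning of entries below 1e-5 (renormalizing again), so the matrix stays
column-stochastic throughout. Iteration stops when the maximum entrywise
change drops below 1e-6 or after 100 iterations; non-convergence returns the
current partition with a warning flag rather than failing. Clusters are read
as connected components of the supra-threshold support of the converged
matrix. This interpretation is equivalent to the usual attractor reading on
converged matrices, is deterministic, covers every node exactly once, and by
construction can never join nodes from disconnected components of the input
graph. Inflation 2.0 sits mid-range of ortholog-clustering practice; raising
it fragments clusters, never merges them (verified empirically in the test
suite).

Collapsing clusters to matrix rows counts a family present in a genome when
the cluster holds at least one protein from it, so within-genome paralogs
contribute a single presence.

## Partitioning and summary conventions

A family is core iff present in all G genomes, unique iff present in exactly
one, accessory iff present in ≥ 2 and < G. With G = 1 every family is both
"in all" and "in exactly one"; such runs are classified core and flagged
degenerate to keep the subsets disjoint.

Two reporting conventions matter for matching published tables of this kind
and are therefore explicit:

* subset percentages are **truncated** to two decimals (892/2,609 →
  34.18%, 449/2,609 → 17.20%; rounding would give 34.19/17.21), computed
  exactly via rational arithmetic;
* genome summary statistics (size, GC%, CDS) use the **population** SD
  (divisor n), which reproduces ±0.10 Mb / ±0.12% on the nine-strain table,
  where the sample SD would give 0.11/0.13;
* the integer quotes of the fitted asymptotes drop the fractional part
  (1182.675 → "about 1,182 genes"), the same truncation convention.

## Accumulation curves

Genome orderings are uniform random permutations from a seeded
`numpy.random.Generator`; the default is 100 permutations with the median as
aggregate (both configurable, and small genome sets can enumerate all G!
orders exactly). For each order we track pan(N), core(N) and new(N) =
families first seen at position N; per permutation, pan is non-decreasing,
core non-increasing, and new sums to the final pan size — these invariants
are property-tested.

## Model fitting

**Heap's law** is fitted by ordinary least squares of log n on log N. On
noise-free power-law data this is exact; with additive noise it is the
standard estimator for this model and keeps the openness call deterministic.
A boundary band |α − 1| ≤ 1e-9 is reported as "boundary" instead of forcing
an open/closed call.

**Offset exponential** `n = k·exp(−x/t) + tgθ` is fitted by separable least
squares: for fixed t, (k, tgθ) is a linear problem solved exactly; t is
scanned on a 200-point log-spaced grid from 1/50 of the x-step to 50× the
x-range, and the best grid point is refined by bounded scalar minimization
between its neighbours (absolute tolerance 1e-9). This is deterministic and
globally robust — no starting values, no convergence-to-local-minimum
failure mode of generic nonlinear optimizers on this ill-conditioned
3-parameter family. On exact model data with t between 0.5 and 20 the
parameters are recovered to better than 1e-3 relative error (tested).
A constant series leaves t undetermined; the fit returns k = 0 with the
constant as asymptote and an `identifiable = False` flag, which propagates
into the stabilization summary.

## Annotation profiles

Category distributions are percentages over *annotated* subset members;
genes missing from the annotation table are excluded from the denominator
and reported as a separate unannotated count (figure-style category shares
are shares of classified genes). Percentages are rounded to the integer by
default. The adhesin call uses a strict `score > 0.7`; the PPI filter keeps
`score ≥ 0.9765` (a "minimum score" is inclusive). Both thresholds are
configurable. Most-connected nodes break ties lexicographically.

## Synthetic generator

The generator emulates exactly the structure the analysis assumes: a fixed
core, accessory families whose member genomes are drawn uniformly without
replacement at user-specified frequencies (an exchangeable model — no strain
phylogeny or gene-gain/loss process), and per-genome Poisson counts of
strain-specific families. Protein families are i.i.d. uniform seed sequences
over the 20 standard amino acids with per-site substitutions drawn uniformly
over the 19 alternatives; no indels, gene order, or synteny. All draws come
from one seeded stream, so a spec is fully reproducible.

Consequently, passing tests demonstrate correctness of the bookkeeping,
clustering and estimation machinery under this idealized model; they do not
demonstrate robustness to real-data complications (fragmented assemblies,
annotation errors, domain shuffling, highly divergent orthologs, large
paralog families).

## Problem sizes

The test suite and acceptance script run at desk scale by design: nine-point
curve fits (matching a nine-genome study), matrices up to a few thousand
families, clustering fixtures of tens of proteins, and Monte-Carlo suites of
a few hundred seeded replicates — sizes at which the exhaustive and
brute-force oracles used for validation are feasible.

## Known limitations

* Dense-matrix MCL scales as O(n³) per iteration; fine for single-species
  protein sets, unsuitable for metagenome-scale graphs.
* The built-in scorer is not a BLAST substitute: no e-values, no
  low-complexity masking, quadratic candidate screening.
* Heap's-law fitting in log space weights relative error; for series
  spanning many orders of magnitude a direct nonlinear fit would weight
  differently.
* Accessory membership in the generator is exchangeable across genomes;
  real accessory genes are phylogenetically correlated.
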