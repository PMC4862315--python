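# Methods

This note documents the models, parameters and numerical choices behind
`ampelo`, and what the synthetic validation does and does not demonstrate.

## Probe-to-gene remapping

Probes are aligned full-length and ungapped against the transcript set.
The built-in aligner enumerates every placement of the probe on both
strands with Hamming distance ≤ k; it is exact, and for the short-oligo
probes and desk-scale transcript sets this package targets, a seeded
heuristic aligner is unnecessary. Precomputed alignments in the standard
12-column tabular format (BLAST `outfmt 6` dialect) are accepted
interchangeably; records containing gap opens are dropped, because the
tier semantics below are substitution-only. Coordinates are 1-based
inclusive on the transcript. `N` never matches, including against another
`N` — an undetermined base cannot support a claimed identity.

**Tier thresholds.** A hit must cover at least `min_coverage_fraction` of
the probe (default 1.0, i.e., full-length). It is *strong* when
`mismatches ≤ strong_max_mismatch` (default 1) and *weak* when it only
satisfies `weak_max_mismatch` (default 3); anything beyond is discarded.
The defaults mirror the three mismatch classes used in practice when
diagnosing probe sharing on dense 60-mer platforms (perfect/one mismatch
vs. two-or-three mismatches); real platforms differ in probe length and
design quality, so all three values are per-platform configuration, and
the weak tier is explicitly a substitution-count surrogate for whatever
relaxed score (identity, bit-score or E-value based) an external aligner
might use. Multiple placements of a probe within one gene collapse to the
best hit (fewest mismatches, then smallest start); ambiguity is a
gene-level notion, so repeated within-gene placements never make a probe
ambiguous.

**Mapping decisions.** No strong gene → *unmapped* (a weak-only probe
cannot reliably measure anything, and keeping it would let pure
cross-hybridization define measurement units). Exactly one strong gene and
no other weak gene → *unique*. Otherwise → *ambiguous* over the full gene
set. Probes with no surviving hits at all receive explicit unmapped
decisions, so statuses always partition the probe set.

## Gene clusters and measurable transcripts

The ambiguity graph is bipartite (probes vs. genes) with one edge per
surviving tiered hit of every mapped probe. Gene clusters are the
connected components containing ≥ 2 genes. Weak edges participate in
connectivity by default — cross-hybridization is precisely the phenomenon
that makes genes jointly measurable — with a strong-only switch for
sensitivity analysis. Components held together by a single probe are
still clusters (the weakly linked, multi-chromosome case observed on real
platforms).

Classification: *perfect ambiguity* when every cluster probe has a
0-mismatch edge to every cluster gene (the genes are interchangeable for
the platform); *weak link* when deleting weak-tier edges disconnects the
gene set; *partial* otherwise.

Cluster ids are assigned by sorting components on their smallest member
gene id, which makes the whole clustering invariant to probe/hit input
order. Measurable transcripts are singletons (sorted by gene id) followed
by clusters (sorted by cluster id); overlapping clusters are rejected, and
the measurables provably partition the gene universe.

Real compendia finalize clusters with manual curation against probe-level
expression coherence. This pipeline is fully automatic; an optional
consistency filter (off by default) emulates that curation step by
demoting clusters whose mean off-diagonal probe correlation (uncentered
Pearson across contrasts) falls below a configurable floor. Because the
automatic component count depends on the real platform's probe sets,
annotation, and undisclosed per-platform thresholds, published cluster
totals are not a target for this implementation.

## Summarization, contrasts, and the compendium

Inputs are assumed to be normalized log2 signals; within-platform
normalization, background correction and quality control are upstream
concerns, and sequencing samples enter as precomputed per-gene log2
abundances. A singleton measurable takes the median (configurable to
mean) of its uniquely mapping probes; the median is preferred for its
robustness to a single aberrant probe. A cluster measurable takes the
median over *all* probes whose entire gene set lies within the cluster —
this is the point of keeping shared probes. An ambiguous probe whose gene
set straddles measurables (possible when weak edges are excluded from
clustering but not from decisions) contributes nowhere and is logged.

A contrast is `M = test − reference` on the shared defined entries (both
already log2, so M is the log2 ratio). Antisymmetry
`M(t,r) = −M(r,t)` holds by construction and is verified property-wise.
Replicate handling and the choice of which samples to pair are scientific
judgments that vary per experiment; pairings are therefore explicit
input, never inferred.

The compendium stacks contrast columns over the full measurable list;
missing cells are `NaN` in memory and the literal `NA` in the TSV
serialization (written with `%.10g`, which round-trips exactly). The
missing fraction is reported exactly as (# missing cells)/(rows·columns).

## Annotation

The controlled vocabulary is a forest of terms; parentless terms are the
category roots. Cycle and unknown-parent errors name the offending terms.
Sample annotations are (term, value) entries; values normalize
canonically (numeric strings compare as numbers, e.g., developmental
stage "33" equals 33.0), with an optional numeric tolerance. The diff of
a contrast's test and reference annotations splits entries into *shared*
and *changed*; a term present on only one side counts as changed — the
condition did differ between the samples, whichever side recorded it.
Category tallies count a contrast as *unique* for a category when its
changed terms touch exactly one of the configured category roots, and as
*shared* for every touched category when they touch two or more (so
shared counts intentionally double-count multi-category contrasts). The
default roots (development, tissue, biotic treatment, abiotic treatment,
genotype) are configuration, not structure.

## Exploration engine

**Uncentered Pearson.** r = Σxy/√(Σx²·Σy²) over pairwise-complete
positions. For log-ratio data the origin (no change) is meaningful: two
genes that deviate from zero in the same contrasts should score highly
even if their dynamic ranges differ, which mean-centering would distort.
Scores are undefined — never silently zero — below `min_overlap` shared
positions (default 10) or when either vector is all-zero on the overlap;
results are clipped to [−1, 1] against floating-point drift.

**Quicksearch.** Contrasts are scored by the mean |M| over the query
measurables with defined values, requiring defined values for at least
half the query (both parameters configurable); the top-k scores win, ties
broken by contrast id. Mean absolute log-ratio is the natural reading of
"most relevant condition for these genes": strong modulation in either
direction. Query genes inside a cluster resolve to their cluster row,
with a notice.

**Extension ranking.** Candidate genes (or contrasts) are scored against
the module's mean profile restricted to the module's contrasts (genes);
`against="best_member"` substitutes the best single-member correlation.
Modes `correlated` / `anticorrelated` / `both` rank by r, −r, |r|;
undefined scores are excluded; ties break by id.

**Enrichment.** For each annotation term with k ≥ 1 module carriers, the
p-value is the upper hypergeometric tail P(X ≥ k | N, K, n) (scipy), with
Benjamini–Hochberg step-up FDR across all tested terms (statsmodels).
Cluster measurables contribute every member gene's terms, on both the
module and background sides. Terms absent from the module are not tested
(their p-value would be 1 by construction).

**By-expression ordering.** Rows and columns are independently clustered
by average-linkage agglomeration (scipy) on distance 1 − r; pairs with
undefined correlation sit at the neutral distance 1.0. Determinism is
enforced twice: the distance matrix is computed on label-sorted input (so
linkage cannot depend on input permutation), and at every merge the
subtree containing the lexicographically smallest id is placed first. The
display path uses `min_overlap` 3 rather than the search default so small
modules remain orderable.

## Synthetic data

The generator emulates a dense short-oligo design: 1 kb transcripts, four
60 nt probes per gene drawn from the sense strand at uniform random
offsets, a configurable fraction (default 0.25) stored
reverse-complemented to exercise strand handling. Gene families —
mutated copies of a common ancestor under per-site independent
substitution, no indels — produce exactly the shared-probe ambiguity the
pipeline must detect; unrelated random 1 kb sequences essentially never
collide within three mismatches of a 60-mer, so non-family genes stay
singletons. Expression is a per-gene log2 baseline (mean 8, sd 1), plus
planted per-gene effects on planted contrasts in test samples, plus
independent Gaussian probe-level noise. Everything derives from a
mandatory seed and is byte-reproducible.

Ground truth is computed by a deliberately separate route (a positional
Hamming scan plus union-find transitive closure), so agreement between
the generator's partition and the pipeline's clusters is a genuine
cross-check rather than circular.

The planted-recovery study runs at effect 2.0, probe noise sd 0.25, and
50 contrasts (5 perturbed) over 100 seeded replicates; the platform uses
60 genes of length 300 with four probes each — large enough for a
meaningful top-decile criterion (≥ 50 null candidates), small enough to
keep the whole study desk-scale. Success requires quicksearch to rank a
planted contrast first, and a module seeded with half the planted genes
to place every remaining partner in the top decile of ranked candidates.

**What passing does not show.** The simulator has no dye bias, probe
GC/affinity effects, saturation, batch structure, or indel variation, and
its noise is homoscedastic Gaussian. Recovery rates here demonstrate that
the machinery is correct and well-calibrated on its own model, not that
real cross-platform compendia reach these accuracies; on real data the
dominant error sources are normalization quality and annotation drift,
both explicitly out of scope.

## Numerical and degenerate-input choices

- Correlation undefined (not 0) below the overlap floor and for all-zero
  overlaps; undefined candidates are dropped from rankings, undefined
  pairs omitted from networks.
- Hypergeometric p-values are clipped into (0, 1] before FDR adjustment.
- Single-row or single-column modules order as identity; empty modules
  are an error.
- TSV matrices use `%.10g` (round-trip exact under re-parsing); missing
  is `NA`.
- All tie-breaks (contrast/gene ranking, cluster ids, leaf ordering) are
  lexicographic, making every pipeline output invariant to input order
  and byte-identical across reruns of the same seed/config.
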