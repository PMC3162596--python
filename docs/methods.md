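# Methods

This note documents the statistical procedures implemented in `xtissue`,
the defaults chosen where the underlying workflow left them open, and the
limitations a user should know before trusting a result.

## Study design assumptions

The pipeline targets the single-profile-per-tissue design: each tissue is
one pooled library (RNA-seq) or one array. There are no biological
replicates anywhere in the model, which shapes several choices below —
most importantly the enrichment test's degrees of freedom and the
permutation scheme in GSEA. Replicate-aware differential expression is
deliberately out of scope.

## Quantification

RPKM for a transcript with `C` mapped reads, length `L` bp, library size
`N`: `10⁹·C/(N·L)`. A transcript is *detected* with ≥1 mapped read. The
expression cutoff retains transcripts with RPKM **strictly greater** than
the threshold (default 10); strictness matters only for exact-boundary
values and is applied consistently. Abundance profiles assign each
transcript to the highest category whose lower count limit it reaches
(top category unbounded); the dynamic range is `log10(max/min)` over
detected transcripts.

## Cluster collapsing and homolog projection

Transcripts are collapsed to gene clusters by the **maximum** RPKM over
the cluster's transcripts, and probe signals likewise by the maximum per
cluster and tissue. Projection across species replaces each source
cluster by the **first** target in its homolog list; sources without
homologs drop out and duplicate targets are deduplicated keeping the
first occurrence. Three conventions are this package's own, since a
retrieved mapping's original order is generally unrecoverable:

* without an explicit rank column, targets are ordered lexicographically
  (a rank column, when present, wins);
* when several sources project onto one target in a matrix, the maximum
  value is kept, consistent with the max-representative convention;
* transcripts without cluster assignment are dropped (and counted in the
  log) rather than treated as singleton clusters.

## Tissue-enrichment selection

For a gene with target-tissue value `x̄` and comparison values
`y₁…yₙ` (n = 3 in the four-tissue design), the statistic is

    t = (x̄ − µ) / (s/√n),   µ = mean(y), s = SD(y) (n−1 denominator)

with a **one-sided** upper-tail p from Student-t with `n−1` df. One-sided
because only enrichment (not depletion) is selected, at α = 0.025 — the
one-sided twin of a two-sided 0.05. A gene is enriched when `p < α`
*and* its target value exceeds both the RPKM floor (10) and its mean over
all compared tissues (target included). Genes whose comparison values are
all zero have undefined p and are flagged *exclusive*; they are admitted
by default (a flag disables this) because exclusivity is the extreme form
of enrichment. Zero spread with nonzero comparisons is flagged degenerate
and never selected.

**Known limitation — anticonservative null.** The statistic treats a
single observed value as a sample mean. Under an exchangeable null
(target and comparisons iid), `(x − ȳ)/(s_y/√3)` is distributed as
`2·t₂`, not `t₂`: the numerator has standard deviation `σ·2/√3` while the
denominator estimates `σ/√3`. The realised per-gene false-positive rate
at α = 0.025 is therefore ≈ 8% (≈ 10% with log-normal noise), not 2.5%.
With thousands of null genes the enriched list consequently contains a
substantial false-positive fraction; on synthetic data at the reference
design the selection reaches sensitivity ≈ 0.93 but planted-truth
precision ≈ 0.42. This is a property of the method being implemented,
reproduced faithfully; the acceptance suite records the measured values
rather than hiding them. Users needing calibrated selection should treat
the p-values as ranking scores, not error rates.

## Ontology statistics

Over-representation of a term with `K` background carriers in a list of
`n` genes from a background of `N`, with `k` carriers observed, is the
one-sided hypergeometric tail `P(X ≥ k)`. The EASE variant computes
`P(X ≥ k−1)` (floor 0), penalising single-gene support; it is never
smaller than the plain tail. FDR across terms is Benjamini–Hochberg
(via statsmodels). Terms without background carriers are skipped.
Classification counts a gene once in every category annotating it, with
an "unknown function" bucket per namespace; the energy distribution
contrasts per-category gene-count shares with summed-RPKM shares,
multi-category genes contributing fully to each category and unannotated
genes reported as "unclassified". Ancestor propagation over the ontology
graph is intentionally not performed — annotation tables are taken as
given.

## Preranked GSEA

Walking a ranked list of `L` genes with `H` gene-set hits, the running
sum gains `|score|^w / NR` at a hit (`NR` = sum of hit weights, `w` = 1 by
default; `w` = 0 gives the classic Kolmogorov–Smirnov form) and loses
`1/(L−H)` at a miss. ES is the extremum of maximal absolute deviation; an
exact tie between the positive and negative extremum resolves to the
negative one. The leading edge comprises hits at or before the maximum
(positive ES) or at or after the minimum (negative ES).

Null ES values come from **gene-label permutation** — set membership
reassigned uniformly among ranked genes, preserving set size. With one
profile per tissue there are no sample labels to permute, so
phenotype permutation is impossible in this design; gene-label
permutation is the standard preranked fallback. Nominal p is the
add-one-smoothed exceedance fraction among same-sign nulls,
`(b+1)/(m+1)`; NES divides ES by the mean |null ES| of the same sign; q
follows the standard pooled-normalised-null FDR with positive and
negative tails handled separately, clipped to [0, 1]. The permutation
engine evaluates extrema only at hit peaks and preceding valleys (the
running sum is monotone between hits), which makes 1000 permutations on
thousand-gene lists effectively free; it is verified exactly against the
full running-sum evaluation.

Ranking metrics: enriched-gene lists are ranked by `−log10 p`, with
exclusive genes placed above the best finite score by a fixed increment
of 1. Target-tissue lists for the cross-species comparison are ranked by
`log2((target + ε)/(mean others + ε))` with pseudocount ε = 1 — a
tissue-specificity ratio; ranking by absolute intensity is also possible
by constructing the ranked list directly. Gene sets are filtered to an
intersection of ≥ 5 ranked genes by default (no upper bound).

The cross-species matrix scores every query tissue's projected enriched
set against every target tissue's ranked list, each cell holding (NES,
FDR q, nominal p); cells whose query set intersects the list below the
size floor are marked not assessable and the run continues. Per-target
seeds are spawned deterministically from the global seed.

## Synthetic data generator

The generator emulates the pooled multi-tissue design: per-gene log-normal
baseline abundance; disjoint planted enriched modules multiplied by
`2^log2_fold` in their tissue; mean-one multiplicative log-normal noise
with coefficient of variation `noise_cv`; transcript lengths uniform in
`length_range_bp`; Poisson read counts with mean `rpkm·L·N/10⁹`; a
homolog map with exact coverage and multi-target fractions; annotation
terms with exact planted overlaps and an exact unannotated fraction.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| `baseline_log_mean`, `baseline_log_sd` | 2.84, 1.8 (ln RPKM) | matches published bulk-tissue summaries: ~62% of detected transcripts above 10 RPKM and a ~5-decade dynamic range |
| `noise_cv` | 0.25 | free parameter: with one pooled library per tissue no replicate variance is estimable from data; 0.25 is a moderate between-tissue biological variation |
| `log2_fold` | 3 | an 8-fold planted enrichment, comfortably inside what tissue-restricted genes show |
| `total_reads_per_tissue` | 10⁷ | depth at which Poisson noise is negligible for genes above the RPKM floor |
| `n_genes`, `n_enriched_per_tissue` | 5000, 200 | a 4% planted fraction per tissue, keeping planted and null populations both large |
| `homolog_coverage`, `multi_homolog_fraction` | 0.7, 0.2 | typical fish→mammal Unigene mapping coverage with a moderate many-to-many share |
| `unannotated_fraction` | 0.4 | the unannotated share reported for less-studied genomes |

What the generator does **not** emulate: replicate structure, count
overdispersion beyond the abundance-layer noise (counts are Poisson by
design, keeping the count model single-parameter), isoform structure,
read-level artefacts, correlated gene modules beyond the planted sets,
and biased homology (mapping is independent of expression). Passing tests
on synthetic data therefore demonstrate algorithmic correctness and
recovery under the stated model, not robustness to real-data artefacts.

Determinism: one seed drives everything; sub-streams for counts, the
homolog map, annotations and the two-species pair are spawned from
`(seed, stage)` seed sequences, so an identical configuration yields a
byte-identical fixture bundle.

For the two-species comparison fixtures, `generate_species_pair` draws
the noise-free planted profile once and applies two independent noise
realisations, projecting the second through the generated homolog map —
matched tissue biology, independent measurement, which is the premise the
cross-species comparison is meant to detect. Problem sizes used in the
acceptance checks (1,200 genes, 3 tissues, 60 planted per tissue, 1000
permutations, 10 runs; recovery at 5,000 genes over 5 seeds) were chosen
as the smallest designs at which the statistics of interest are stable.

## Numerical conventions

* Ranked-list ties break lexicographically by gene id; selection output
  orders by descending target RPKM then id — all orderings deterministic.
* Tables are tab-separated UTF-8, single header line, `NA` for missing;
  floats written with `%.10g` so reruns are byte-identical.
* Hypergeometric/EASE tails and the Student-t tail delegate to scipy;
  both are verified against exact integer enumeration (all tables with
  N ≤ 60) and high-precision numerical integration respectively.
* Degenerate inputs: all-zero gene-set weights fall back to equal hit
  weights; an empty ranked-list intersection, a missing matrix column, or
  a non-subset gene list raise typed errors naming the offender.
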