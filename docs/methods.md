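# Methods

This note documents the models, rules and numerical choices behind
`mirforge`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the design was genuinely open.

## The consensus cascade

Candidates arrive as per-tool GFF3 files with a score attribute. The cascade
applies, in fixed order:

1. **Per-tool ingestion gates.** Each tool's calls pass a per-tool minimum
   score (default 5.0 for conservation-based tools, none for the
   expression-based predictor, whose dedicated rule comes next). This
   represents the per-tool significance thresholds that external predictors
   (covariance-model search, homology search) apply on their own scales; the
   thresholds are ours to enforce at ingestion because the tool runs
   themselves are outside the pipeline.
2. **Gap-free re-anchoring.** Every candidate hairpin sequence must be
   located in the genome without gaps (≤ 1 substitution by default).
   Implementation: the stated interval is verified first (ties always resolve
   to it); otherwise an exact-search/pigeonhole seed-and-extend scan over all
   contigs and both strands finds placements, preferring the leftmost.
   Candidates with no gap-free placement are dropped and logged.
3. **Reliability rule** (expression-based predictor only): keep a candidate
   iff it has a reference-miRNA homology hit with ≤ 1 mismatch and no gaps,
   or its score is ≥ 7.0 (inclusive). Scores of different tools are not
   comparable; only this tool's score participates in the rule.
4. **Homology-hit filter** (applied to externally produced hit tables): a
   hit counts only if it spans ≥ 90 % of its query, has zero gaps, and its
   significance is strictly below 10⁻⁷; redundant hits per
   (candidate, reference) pair keep the best significance.
5. **Overlap deduplication.** Loci overlapping or separated by an edge gap
   < 100 nt on the same contig are grouped by single linkage, regardless of
   strand (opposite-strand calls at one position are the same physical
   hairpin). The highest-scoring member survives; ties prefer the interval
   supported by more tools, then the leftmost. The union of supporting tools
   and the union span (`group_span`) of the group are recorded. "Within
   100 nt" is read as *edge gap*, not midpoint distance.
6. **Extension triage.** Each locus, extended by 50 nt on both sides, is
   looked up in an externally produced structure-comparison table; verdicts
   `mirna_structure_hit` and `no_hit` keep the locus, `other_ncrna_hit`
   discards it. A missing table entry is treated as no-hit with a warning.
7. **Annotation conflicts.** Loci overlapping non-miRNA ncRNA genes or
   same-strand exons are removed; intronic and antisense placement is
   allowed. This reconciles two facts about miRNA geography: annotation
   pipelines must purge candidates that are really fragments of other
   ncRNAs, yet roughly half of genuine miRNA genes sit inside protein-coding
   genes (usually introns). The conflict classes are configurable.

## Expression verification

The read-profile classifier formalizes what a curator checks in a genome
browser. Over each locus ± 20 nt flank, using the `group_span` of the merged
locus as the window (the dedup winner may be a mature-length call; profiling
only that 22-nt interval would misread the other arm's reads as flank
coverage):

- `no_expression` if total reads < `min_reads` (default 5);
- `rejected_extended` if flank coverage beyond a 5-nt edge tolerance exceeds
  10 % of the peak height (the degraded-transcript signature); the edge
  tolerance exists because genuine mature products overhang annotation
  boundaries by a few nucleotides;
- `rejected_diffuse` if more than 2 blocks overlap the locus, or no block
  reaches sharpness 0.6, or the inter-block gap carries coverage above 10 %
  of the smaller block height;
- `verified` otherwise; mature arms are annotated from the modal read
  interval (most frequent 5′ position × most frequent read length) of each
  sharp block, clipped into the locus, with 5p/3p assigned strand-aware.

All shape thresholds are fractions of observed heights, so verdicts are
invariant to sequencing depth; only `min_reads` is absolute. The defaults
(min_reads 5, sharpness 0.6, gap/flank fractions 0.1) are this module's
formalization of a manual curation step — chosen as loose values that
separate the generator's rectangular positives from its extended negatives
cleanly, and all configurable because real curation thresholds are never
published.

A locus is catalogue-verified if **any** library verifies it (expression can
be tissue-restricted); an extended-mapping verdict in one library dominates
silence in others. Unexpressed loci supported by a conservation-based tool
(or homology-rescued) are kept as `putative_unexpressed`; unexpressed loci
with only read-based support are removed.

**Read blocks.** Blocks are built by overlap-chaining of collapsed reads
(merge gap 0) with a *sharpness* statistic — the fraction of reads whose 5′
ends fall within ± 2 nt of the modal 5′ position. This deliberately replaces
Gaussian-kernel block decomposition: the pipeline uses blocks only as a
binary expression/shape gate, for which chaining + sharpness is sufficient
and exactly testable.

## Catalogue structure

- **Clusters**: single-linkage chaining of catalogue entries along a contig
  with edge gaps ≤ 10 kb (inclusive); at least two members; strand ignored
  for membership. Distance is the edge gap between precursor intervals, not
  midpoints, consistent with interval semantics elsewhere.
- **Families**: identity = matches / length of the shorter sequence under
  ungapped sliding alignment of the shorter into the longer (matures are
  near-equal length; this avoids bundling an aligner). Known-family
  assignment requires identity ≥ 0.9 **and** an identical seed (nt 2–7);
  ties break to the highest identity, then the lexicographically smallest
  family name. Unassigned entries are partitioned into novel families by
  single-linkage clustering at the same 0.9 threshold, labelled NF0001… in
  genomic order. The 0.9 + exact-seed rule is a documented default, not an
  empirical constant — published catalogues state only "sequence identity".
- **Composition strings**: 5′→3′ family labels of cluster members joined by
  `/` (e.g. `29a/29b`); a reversal flag reflects the string for the analyst.
  Detecting repeat patterns in these strings is left to the analyst.

## Target prediction and enrichment

Sites are exact 6-mer matches of the reverse complement of the mature seed
(nt 2–7) that occur ungapped at the *same alignment columns* in every
required species row of an orthologous 3′-UTR alignment; cross-species
conservation is the false-positive filter, and requiring more species
(e.g. adding mouse and human to the two fish) can only shrink the target
list. 7mer-m8/7mer-A1 site variants are deliberately out of scope — the seed
region is the primitive here.

The enrichment p-value is the upper hypergeometric tail, computed in log
space via `gammaln` and verified against exact big-integer rational
enumeration (≤ 10⁻¹² relative error over an exhaustive lattice of valid
(N ≤ 60, R, n, r)) and against `scipy.stats.hypergeom.sf` at large N. Two
analysis modes: *set-level* (N = gene universe, n = genes with any site) and
*per-miRNA* (N = genes with any site, n = genes with this miRNA's site).
BH adjustment is applied within each analysis family and significance is
gated on the adjusted value at 0.05 (the natural reading of an
"adjusted, then significant below 0.05" procedure).

## Expression phylogeny

Presence = expressed in ≥ 1 library of a species at `min_reads`. Distances
are Jaccard on presence sets (or proportion of differing characters on
concatenated mature sequences with pairwise gap deletion — both modes are
provided because either characterization of "based on the expressed miRNAs"
is defensible). Trees are average-linkage hierarchical clustering; branch
support is the percentage of `n_boot` ordinary nonparametric bootstrap
replicates (miRNA columns resampled with replacement) containing each
original bipartition. Ordinary bootstrap proportions replace multiscale/AU
resampling deliberately: supports are reported as plain percentages and the
ordinary bootstrap is simpler to verify. Species are canonicalized to sorted
order, making results invariant to input row order.

## The synthetic-data generator

The generator *is* the study design; its defaults are the conditions under
which the pipeline's guarantees are stated.

- **Genome**: uniform-random contigs (4 × 1.5 Mb) with planted hairpins —
  precursor length 60–120 nt, two 22-nt mature arms separated by a 10–15 nt
  loop, the 3p arm a ≤ 3-mismatch reverse complement of the 5p arm; strands
  uniform; no thermodynamic folding is simulated (folding was the job of the
  external predictors, whose *output* the pipeline consumes). Declared
  clusters are laid out with exact intra-gaps; all other spacings are
  ≥ 15 kb so only declared clusters chain at the 10-kb rule. Decoy loci are
  plain background intervals.
- **Tool calls**: five emulated predictors (one expression-based, one
  mature-length homology tool, three precursor-length conservation tools),
  each detecting a true locus with sensitivity 0.8 and calling a decoy with
  probability 0.1 by default; true-call scores ~ N(10, 2), false-call scores
  ~ N(3, 1.5), so true loci stochastically clear the ≥ 7 rule and decoys
  rarely do; positional jitter is configurable (default 0).
- **Reads**: per expressed arm, Poisson(30) collapsed reads starting within
  ± 2 nt of the arm 5′ end (60 % exactly on it), lengths within ± 1 nt —
  the rectangular two-block signature. A configurable fraction of loci
  (default 5 %) instead get uniform coverage across precursor ± 50 nt
  (extended-mapping negatives); by default 80 % of the remainder are
  expressed and the rest silent, echoing the typical fraction of predictions
  that show expression. Reads are emitted collapsed (BED6 count column).
- **UTRs**: per gene, an ancestral 200-nt sequence mutated at 5 % per
  species; planted sites are written at identical columns of all conserved
  species rows. Site carriage is `site_base_rate` (0.12) for background
  genes and odds-scaled for the designated DE set, so `enrichment_odds = 1`
  is the exact null. Chance conserved 6-mers inherited from the ancestral
  sequence occur (~2–5 % of genes) and are independent of DE labels.
- **Species expression**: presence evolves on the planted tree from an
  all-present root, with loss/gain probabilities per *unit branch length*
  (1 − (1 − p)^L on a branch of length L). The default 7-taxon tree is
  ultrametric (every leaf at depth 4), making the presence process
  clock-like — the regime in which average-linkage clustering is a
  consistent estimator of the topology. Default rates: loss 0.15, gain 0.02
  per unit length. Two replicate libraries per species with Poisson(30)
  counts for present miRNAs.

What the generator does **not** emulate: sequencing error profiles,
quality-score realism beyond threshold behavior, multi-mapping ambiguity,
assembly artifacts, realistic base composition or folding energetics, and
rate heterogeneity across lineages. Passing tests therefore demonstrate that
the *rules* are implemented correctly and are well-calibrated against their
own stated signatures — not that the thresholds are optimal for any
particular real dataset.

## Problem sizes used in validation

The validation studies use 200 planted loci + 100 decoys for end-to-end
recovery; 400 genes (80 DE) with one miRNA and two conserved species over
200–400 replicates for enrichment calibration; and 750 presence characters
(catalogue scale) with 200 bootstrap replicates over 50 seeded simulations
for tree recovery. Character count matters for tree support: at 200
characters the planted topology is usually recovered but deep-edge supports
are unstable; at catalogue scale (≥ 600 characters, matching the size of a
real miRNA catalogue) all supports concentrate near 100.

## Numerical and degenerate-input choices

- Quality trimming is hard clipping from both ends (not sliding-window),
  iterated with adapter clipping to a fixpoint so trimming is idempotent.
  Adapter matching tolerates 1 mismatch per 10 compared bases and accepts
  ≥ 8-nt adapter prefixes at the read 3′ end. Qualities are Phred+33.
- Tie-breaks are deterministic everywhere: dedup winners (score, tool count,
  leftmost), block modes (count, then smaller coordinate), family ties
  (identity, then lexicographic), novel-family labels (genomic order).
- Empty inputs propagate cleanly: empty candidate sets yield an empty
  catalogue with a zero-count manifest; an empty gene universe or gene sets
  outside the universe are input errors; p-values outside [0, 1] are input
  errors.
- The hypergeometric tail returns exactly 1.0 whenever r is at or below the
  lower support bound max(0, n − (N − R)).
- All generators derive their random streams from the config seed plus a
  fixed stage offset; identical configs give byte-identical output files.

## Known limitations

- The per-candidate audit records one (the first) removal rule per
  candidate; a candidate failing several rules is attributed to the earliest
  stage only.
- Sequence-mode species distances are degenerate on the synthetic matrices
  (the generator plants no per-species mature-sequence divergence), so tree
  validation uses presence mode.
- The structure-triage comparison engine and all external predictors are out
  of scope by design; the pipeline consumes their outputs in standard
  formats.
- `putative_unexpressed` entries carry the hairpin sequence in place of an
  (unknowable) mature; family assignment still works through sliding
  identity but is less specific than for verified entries.
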