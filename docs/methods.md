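# Methods

## The problem and the model

Droplet single-nucleus RNA-seq tags every cDNA with a 16-nt cell barcode
and a 10-nt UMI. Long-read sequencing of the same cDNA pool preserves full
transcript structure but garbles the tags: at a per-base accuracy of ~95%,
a 26-nt tag carries on average more than one error, and direct matching
against a barcode whitelist fails for a large fraction of reads. The
package's central assumption is that the *accurate* short-read library
made from the same pool enumerates essentially all real (barcode, UMI)
combinations together with the genomic neighbourhood of their molecule.
Rescue then becomes a constrained nearest-neighbour search: for a long
read mapped at locus *x*, only combinations whose guide record falls near
*x* are plausible, and the best of those under a local-alignment error
metric is the read's tag.

This assumption has two consequences worth keeping in mind. First, a
molecule sampled *only* by the long-read library can never be rescued —
the short-read library defines the search space. Second, guide records
are trusted as ground truth; short-read sequencing errors in barcodes
would propagate. Both match how the data are produced in practice
(short-read depth is much higher) and both are emulated by the synthetic
generator, which emits guide records error-free.

## Barcode/UMI rescue

* **Chimera filter.** An unmapped flank > 150 nt marks a chimeric read.
  Because the barcode-bearing end legitimately carries
  adapter (30) + barcode (16) + UMI (10) ≈ 56 structural nt inside its
  soft clip, the filter grants a configurable `structural_allowance`
  (default 56 nt) to the *larger* flank only; setting it to 0 restores
  the literal 150-nt rule. The boundary is strict: a 150-nt clip is kept,
  151 is dropped.
* **Binning.** Guide records live in non-overlapping 500-bp bins
  (`floor(position / bin_size)`); a lookup over the read's mapped span
  returns the bins it overlaps plus one adjacent bin on each side
  (`adjacent_bins` configurable). Binning is a search-space reduction,
  not an approximation of the alignment itself: on synthetic data the
  binned result equals exhaustive search over the same candidates
  exactly, and differs from a *genome-wide* exhaustive search only when
  a spurious record far from the locus happens to match the flank better
  (measured at 2/500 reads at 5% error — and in both observed cases the
  binned answer, not the global one, was the truth).
* **Seeding.** A candidate/flank pair is aligned only if they share an
  exact 7-mer, mirroring the word-size gate of a heuristic aligner. A
  `use_seed=False` path forces exhaustive alignment and is used by the
  oracle tests.
* **Scoring and errors.** Smith–Waterman with match +1, mismatch −1,
  gap open 0, gap extension −2 per gap base (a linear gap penalty). The
  26-nt query (barcode ⊕ UMI) is aligned against both flanks and their
  reverse complements, since the cDNA orientation of any given read is
  unknown. The error count is mismatches + gap bases inside the optimal
  local alignment + unaligned query bases, so a truncated tag counts its
  missing bases. Errors are attributed to the barcode (query positions
  0–15) or UMI (16–25) segment; a gap-in-query column is attributed to
  the last query base consumed before it. Numerical conventions, needed
  for exact reproducibility: the optimum cell is the first best in
  row-major order, and traceback prefers diagonal, then gap-in-query,
  then gap-in-target. The kernel is a numba-compiled full matrix; an
  independent plain-Python implementation in the test suite checks score
  and error counts on random pairs.
* **Acceptance rule.** Minimal total errors wins; the winner must be
  unique among distinct (barcode, UMI) pairs — the same pair reachable
  through several alignments is one molecule, not a tie — and must have
  ≤ 3 barcode errors and ≤ 3 UMI errors. Every non-assigned read carries
  a reason (`no_candidate`, `ambiguous`, `over_threshold`, `filtered`).
* **Consensus.** Reads sharing (barcode, UMI, gene) are collapsed: the
  longest read (ties by read id) is the backbone, the others are
  globally aligned to it with edlib, and each backbone column takes the
  majority base with ties keeping the backbone base. Gap majorities
  delete a column and insertion majorities add one, so backbone
  insertion/deletion errors are also corrected. This is a deliberate,
  interface-compatible stand-in for partial-order-alignment polishing;
  on five 5%-error copies of a 200-nt template the consensus is closer
  to the template than any single copy in ≥95/100 seeded trials.

## Counting, splicing and APA

* **Intron-tolerant gene assignment.** Nuclear reads are largely
  intronic, so a read is assigned to a gene when all its aligned blocks
  fall inside the gene's full span (exons ∪ introns) on the matching
  transcript strand; overlap with more than one gene span is ambiguous
  and unassigned. This replaces the alternative of stripping intronic
  segments and re-aligning: the intent — count intron-containing reads
  toward their gene — is identical, without a re-alignment round trip.
* **QC.** Genes detected in fewer than 3 nuclei are dropped first, then
  nuclei with detected-gene counts outside [350, 2300] (root preset;
  an endosperm preset uses [400, 3000]). Bounds are inclusive; the
  filter is idempotent.
* **Splicing calls.** The mapping ratio of an intron is the fraction of
  its bases covered by the molecule's aligned blocks; a ratio strictly
  above 0.5 retains the intron, and one retained intron makes the
  molecule unspliced. Introns entirely outside the aligned span are
  *unobserved* — absence of coverage is not evidence of splicing — and
  count neither way. Intronless genes' molecules are fully spliced
  mRNAs and count as spliced in the incompletely-spliced ratio (a flag
  excludes them instead). The per-nucleus ratio is undefined (absent),
  not zero, for nuclei without molecules.
* **APA features.** A molecule's polyA site is its strand-aware aligned
  3′ terminus. Sites are clustered per (gene, strand) — not
  genome-globally, which could merge convergent genes — by single
  linkage with a 24-nt gap threshold (gap of exactly 24 merges, 25
  splits; chains merge transitively). The cluster representative is the
  median member, lower-of-two-middles for even sizes. Matrices are built
  from per-UMI molecules (one vote per molecule), not raw reads.
* **Conservation.** For every gene, the splicing-layer column sums, the
  APA-layer column sums and the molecule count agree; this is asserted
  on every synthetic run.

## Multilayer integration and tests

Each layer is independently depth-normalized per nucleus to the layer's
median depth, log1p-transformed and feature-standardized, then the blocks
are concatenated over the nuclei present in all layers. Standardization
gives layers equal per-feature weight so the wide APA block cannot drown
the abundance block; `layer_weights` rescales blocks if wanted.
Clustering is PCA (default 30 components) → kNN graph (15 neighbours,
weights 1/(1+d)) → Louvain at resolution 1.0 with a fixed seed.

Cell-type annotation scores each nucleus per type as the mean normalized
expression of the marker set minus a control set matched on expression
bins (25 bins, control up to 50× the marker set — conventions of the
standard cell-scoring approach, declared here because no canonical values
exist); the argmax type is assigned when its score is positive, otherwise
`unknown`, and clusters take their modal type. Differential splicing
between two clusters uses the two-sided Fisher exact test on the
(spliced, unspliced) × (cluster A, cluster B) table (zero-margin tables
are degenerate, p = 1); ratio shifts use a one-sided two-sample KS test
with the alternative that the cluster's ratios are stochastically
greater. Cluster-enriched genes are Wilcoxon-ranked against the rest and
filtered to genes detected in ≤ 25% of out-group nuclei with fold change
≥ 1.5.

## The synthetic generator

The generator is first-class, tested code and defines the conditions all
recovery claims are made under. It emits a one-chromosome genome with
multi-exon genes (1–5 introns, ≥ 2-kb spacing so 500-bp bins never mix
neighbours), a barcode set, error-free guide records (one per molecule),
and long reads structured as
adapter(30) + barcode(16) + UMI(10) + polyT(20) + revcomp(cDNA), pushed
through an i.i.d. error channel at 5% per base split
substitutions : insertions : deletions = 2 : 1 : 1 (configurable). Reads
are emitted with their true alignments (SAM), so no external aligner is
needed; every read and nucleus carries a truth row. Cell types are
planted as marker-gene expression programs (default 5 markers per type
at 8-fold uplift) and/or per-type intron-retention probabilities; the
retention-only contrast uses 0.1 vs 0.9, the regime in which isoform
layers visibly improve clustering.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: homopolymer-biased or signal-level error
structure, ambient RNA, doublets, barcode errors in the short-read
library, variable transcript 5′ truncation from degradation, and
antisense or internally-primed artefacts. Recovery rates on real data
will be lower than the synthetic ≥95%; the synthetic results validate
the algorithmic machinery, not platform-specific error models.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale instances chosen to make every
stochastic property overwhelmingly determined: 2,000 reads / 100 nuclei
for recovery, 500 reads / ≤ 50 candidates for oracle equivalence, 300
nuclei for the multilayer-gain contrast, 40 nuclei × 500 molecules for
ratio recovery (binomial s.e. ≈ 0.022, tolerance 0.05), 1,000 random
pairs for the alignment oracle, and exhaustive enumeration of all 2×2
tables with total ≤ 40 for the Fisher check. Seeds are fixed throughout;
the simulation is fully deterministic given its seed (byte-identical
outputs). Degenerate inputs are defined rather than left to chance:
empty matrices round-trip, QC that removes every nucleus raises instead
of returning an empty success, zero-margin Fisher tables return p = 1,
and a nucleus with no molecules has no ratio rather than ratio 0.

## Known limitations

* The assignment search is exact only within the binned candidate space;
  a guide record of a *different* molecule far outside the bins can, at
  high error rates, align better than the true in-bin record (≈0.4% of
  reads at 5% error). These reads would be mis-assigned by a genome-wide
  search too; binning actually suppresses most such spurious matches.
* Consensus polishing is column-wise majority, not full partial-order
  alignment; with two supporting reads the backbone dominates.
* The incompletely-spliced ratio equals the planted per-intron retention
  probability only for single-intron, non-truncated molecules; with
  multiple introns or 3′ truncation upstream of an intron the molecule-
  level unspliced probability differs from the per-intron rate by
  construction (1 − (1 − r)^k over observed introns).
* Louvain community detection fixes no cluster count; resolution 1.0 can
  over-partition weakly structured data. The multilayer claims are about
  agreement with planted structure (ARI), not about a specific k.
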