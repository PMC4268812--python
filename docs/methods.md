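# Methods

`pantrio` re-implements, as a tested library, the comparative pipeline used
to partition three related genome assemblies into shared and specific
content: whole-genome alignment by unique-anchor chaining, canonical k-mer
coverage profiling of unassembled reads, per-base Venn-sector
classification, coverage-filtered genome-specific region calling, and
majority-rule gene sector assignment.  This note records the models, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmark does and does not demonstrate.

## Whole-genome alignment

Alignment between two assemblies proceeds in four stages.

**Anchoring.** Anchors are maximal exact matches of at least `min_match`
(default 30) bp, found on both strands, that are *unique on the reference
forward strand*: the matched substring occurs exactly once in the
reference.  Uniqueness on the reference side only (rather than in both
genomes) follows the convention of classic MUM-based aligners; a
both-unique mode is available (`AlignerConfig.unique_in="both"`).
Implementation: fixed-length seed words (2-bit packed, so `min_match` is
capped at 32) are indexed over the reference; diagonal-consecutive runs of
seed hits are provably exactly the maximal matches of at least seed length,
and uniqueness is decided by containment of the anchor interval inside an
off-diagonal reference-self maximal match.  N bases match nothing, so N
runs break anchors.

**Clustering.** Anchors of one (reference sequence, query sequence, strand)
group chain when both coordinate gaps are at most `max_gap` (90 bp, the
companion default of the cited aligner family) and the diagonal drift is at
most `diag_band` (5) times the larger gap; clusters whose summed anchor
length falls below `min_cluster` (65 bp) are discarded.  Using the larger
gap in the band test lets a clean 7 bp indel chain into one block (so it is
reported as a single large-indel event) while still splitting wildly
off-diagonal joins.

**Extension.** Gaps between chained anchors are closed by unit-cost global
alignment (match 0, mismatch 1, indel 1; the scoring was not specified
upstream, unit costs are the simplest choice consistent with reporting
substitution and indel *counts*), banded by an edit-distance limit of
`max(|len difference| + diag_band, 35% of the gap, 5)`; the banded solver
is `edlib`.  A band overflow splits the block at the offending gap rather
than forcing a bad join.  Block ends are extended outward one base at a
time while the identity of the extension stays at or above 65%, evaluated
after every added base, then trailing mismatches are trimmed.  A leading
mismatch therefore stops end extension immediately — this keeps
zero-divergence alignments exactly at the boundaries of truly shared
sequence, which the recovery benchmark relies on.

**One-to-one filtering.** The best mutually consistent subset of blocks is
selected with weight = reference span x identity.  Two blocks conflict when
they overlap by more than `overlap_tol` (10 bp, absorbing the few-bp chance
extension at block ends) in reference or query coordinates.  The true
maximum-weight problem is NP-hard in general; each connected component of
the conflict graph is solved exactly by branch-and-bound up to 30 blocks
(component sizes beyond that arise only from dense repeat-vs-repeat block
sets) with a greedy-by-weight fallback above.  Residual sub-tolerance
overlaps among selected blocks are trimmed afterwards, so returned blocks
never overlap.  Difference summarization walks query-sorted adjacent block
pairs: strand change = inversion, different reference sequence =
translocation, out-of-order or an in-order gap beyond `relocation_gap`
(10 kbp; the upstream tooling never defines this cutoff, so it is exposed
as a free parameter) = relocation.  Indel events of more than 5 bp are
reported separately from "substitutions + small indels".

Unaligned regions — the input to the pan-genome classification — use the
*pre-filter*, repeat-inclusive block set, so copy-number differences are
not mistaken for novel sequence.

## K-mer coverage model

Reads are counted as canonical 21-mers (lexicographic minimum of word and
reverse complement; k odd so the canonical form is unique, k <= 31 so a
2-bit packed word fits 64 bits).  k = 21 is long enough that a random
21-mer is not expected to occur in a ~400 Mbp genome, yet short enough to
be robust to sequencing errors.  The mode of the count histogram above an
error cutoff of 10 estimates the single-copy fold coverage; the analytic
expectation is `depth x (1 - (k-1)/read_length) x (1 - error_rate)^k`.

A coverage profile assigns to each position the count of the k-mer
*starting* there (the last k-1 positions of a sequence carry no value, and
region means are over start positions only — one of two defensible
conventions; the other, averaging over covered bases, shifts region means
by well under the tolerances used anywhere here).  Regions with mean
coverage strictly above 100x are classified repetitive; the self-coverage
band for specific regions, [10x, 100x], is inclusive at both ends (the
open/closed choice is not stated upstream and moves no reported value at
realistic coverage).

Presence/absence of a locus in a read sample: positions above the repeat
threshold are masked (so sparse high-copy k-mers inside an otherwise
missing locus cannot rescue it), and the locus is *present* when at least
80% of the remaining positions have coverage >= 10, *absent* at 20% or
below, *ambiguous* between.  The 0.8/0.2 operating points are this
package's choice — the source analysis makes these calls qualitatively
from coverage plots — and are exposed in `KmerThresholds`.

## Pan-genome classification

For a focal genome with partners 1 and 2, let `u1`, `u2` be its unaligned
base sets.  Then specific = `u1 ∩ u2`, core = complement of `u1 ∪ u2`, and
the two pairwise sectors follow by set algebra; the four sectors provably
partition the genome and the implementation verifies this on every call.
Reportable specific regions are maximal runs of the specific label, at
least 100 bp, with mean self k-mer coverage in [10, 100] and mean coverage
strictly below 10 in both partner read sets; coverage criteria are
evaluated on each run as a whole (matching the per-region framing of the
reported tables), not per sliding window.  Genic specific regions
additionally overlap an annotated gene span by at least 100 bp and are kept
whole, retaining flanking promoter/regulatory bases.

Genes are assigned to the Venn sector holding the most exonic bases,
summed across all transcripts (an exon shared by two transcripts counts
twice — "across all possible transcripts").  Ties resolve toward the more
shared sector (core over pairwise over specific, then genome precedence
order): conservative against overcalling novelty.  Shared-sector values in
the seven-sector summary are reported from the first member genome in the
configured precedence order.

Spacing of specific regions along a genome is summarized by
midpoint-to-midpoint gaps (the gap definition is not stated upstream);
the sd/mean dispersion is ~1 when regions are dropped uniformly at random,
the signature of exponential spacing.

## Interval algebra and reporting conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
is converted on read/write.  Interval sets have base-set semantics:
touching intervals merge during normalization.  Annotation categories are
disjointified by precedence CDS > 5' UTR > 3' UTR > non-coding exon >
remaining mRNA, so category bp partition the annotated span; a
non-exclusive mode reports raw overlaps instead.

N50 is the length at which the descending cumulative length sum first
reaches half the total.  Contigs split scaffolds at runs of at least one N
(`--min-gap-run` exposed; the upstream threshold is unstated).  Genome
coverage percentages are printed to one decimal, half-up.  Region tables
report mean length as the integer floor of total/count — the unique rule
consistent with all six published specific/genic-specific means — and the
population standard deviation of lengths rounded to an integer.

## The synthetic trio

The simulator emulates three diverged genomes sharing a common core:
ancestral segments are drawn for each of the seven sectors, a high-copy
repeat family is inserted, gene models are planted inside segments, each
genome concatenates its sectors' segments in an independently shuffled
order (so shared content is relocated, exercising the structural-difference
classification), and shared copies then diverge by per-genome
substitutions and 1-5 bp indels.  Reads are single-end, uniform, with
per-base substitution errors; quality scores are constant.

One deliberate construction detail: a maximal exact match covering a
shared segment would extend past the segment boundary by chance (~1/4 per
boundary per comparison) into a neighboring segment.  When that neighbor is
absent from the partner genome this would blur planted sector boundaries by
1-3 bp.  The simulator therefore assigns the boundary bases of segments
that are absent from some genome via a small inequality-constraint solver
(cliques of size <= 3 over a 4-letter alphabet, solved by iterated repair)
so such extensions are impossible.  This touches at most two bases per
segment, and makes per-base sector truth *exactly* recoverable at zero
mutation rate — the recovery benchmark asserts interval-level equality,
not approximate agreement.

Repeat placement matters for what can be recovered exactly.  By default
all copies of a family are inserted into core segments at ancestrally
shared positions, so every copy is honestly core in every genome.  With
`repeat_in_specific > 0`, copies are also scattered into genome-specific
segments; such copies may chance-align to copies elsewhere in a partner
genome (the extension past the unit makes the match reference-unique), and
the region-level coverage filter will reject the contaminated specific run
— exactly the mechanism by which repetitive "specific" sequence is
excluded from the reported tables.  Because whether a given copy excises
cleanly is luck of the flanking bases, region-level truth comparison on
repeat-scattered trios is done via the repeat-exclusion property (no
called region ever overlaps a planted repeat) rather than Jaccard.

**Reference study conditions** (used by the test suite and the acceptance
script): 1 Mbp core in 20 segments; ten specific segments of 0.5-5 kbp per
genome; a few pairwise-shared segments (2-2.5 kbp); one 50-copy family of
400 bp; ~1 gene per 10 kbp of 0.6-3 kbp; reads 60x, 100 bp, error-free;
divergence either 0 (exact recovery) or 0.005 substitutions/bp per genome
copy plus 0.0005 indels/bp (region calling, Jaccard >= 0.9 against planted
truth; observed ~0.997).  Divergence between shared regions of real
subpopulations is not published for this system; 0.005 per branch (~1%
pairwise) is a realistic within-species figure and is configurable.
Problem sizes were chosen so the whole suite and the acceptance script each
complete in minutes on a single CPU.

**What passing does and does not show.**  The generator produces uniform
random sequence with ideal uniform reads: no GC or coverage bias, no
quality-correlated errors, no nested or diverged repeat families, no
segmental duplications, no paired-end information, and gene models are
structurally simple.  Exact recovery and high Jaccard under these
conditions validate the *logic* of the pipeline (coordinate bookkeeping,
set algebra, thresholds, anchor/cluster/filter correctness), not its
performance on real assemblies, where assembly gaps, diverged repeats and
annotation noise dominate the error budget.

## Known limitations

- Anchor seeds require `min_match <= 32`; uniqueness is forward-strand.
- The one-to-one filter is exact only up to 30-block conflict components.
- Banded gap closure splits blocks rather than aligning through gaps whose
  edit distance exceeds the band; extremely diverged (<65% identity)
  sequence is reported unaligned by design.
- The k-mer engine holds the count table in memory (fine for read sets in
  the hundreds of millions of k-mers; not a disk-backed counter).
- Structural-difference counts (inversions/relocations/translocations) are
  defined operationally from adjacent one-to-one blocks and are not
  expected to reproduce any particular external tool's accounting.
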