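# Methods

## Model and procedure

The pipeline treats circRNA validation as a two-library contrast. A
backsplice junction is a sequence feature unique to the circle; its read
support in a mock (rRNA-depleted total RNA) library measures abundance,
and the ratio of its normalized support in a matched RNase R-treated
library to the mock measures resistance to 3'→5' exonucleolytic
degradation. Genuine circles are resistant; junction-bearing artifacts
(splicing errors, trans-splicing, template switching, tandem duplications)
behave like the linear RNA they come from. Because the false candidates
are linear molecules, the empirical distribution of the host genes' own
canonical (linear) splice-junction ratios is used as the null: the
classification threshold τ is a quantile of that distribution rather than
a fixed fold change, which makes the decision robust to between-sample
differences in RNase R efficiency and sequencing depth.

Coordinates are 0-based half-open on the forward genomic strand
throughout; GTF (1-based closed) and per-pipeline BED dialects are
converted exactly once at ingest.

## Stages and their assumptions

**Merging.** Candidates from different discovery tools are keyed by
`(chrom, start, end, strand)` after dialect normalization; provenance (the
set of supporting tools) is kept because multi-tool support is an
informative prior on validity. An optional tolerance clusters candidates
whose two boundaries each differ by at most *t* bases (single linkage; the
member with the widest tool support, ties broken by smallest coordinates,
represents the cluster). The default is exact matching (*t* = 0): merging
by coordinates presumes the upstream tools were run against the same
genome build, and off-by-one reconciliation is the user's explicit choice.

**Boundary scoring and transcript assignment.** Score 2/1/0 counts how
many candidate boundaries coincide exactly with exon boundaries of a
transcript. Ties among equal-scoring transcripts are broken by
lexicographically smallest transcript id, so reruns are bit-identical; a
seeded random tie-break is available as an opt-in. A candidate whose span
overlaps a transcript only through introns receives that transcript with
score 0 but a degenerate exon chain equal to its genomic span — the chain
is never empty for a placeable candidate, which keeps the sequence
extraction total. Score-1 candidates are spliced over the best-fit exon
chain (recorded in the reference metadata); score-0 candidates use the
unspliced genomic span.

**Junction windows.** Only junction-spanning reads are countable, so the
reference stores a window of half-width *W* around the junction (suffix +
prefix of the circle sequence, junction offset recorded) instead of the
full circle. *W* defaults to the read length; for circles shorter than
*W* the window is the doubled circle, which contains exactly one junction
copy and every substring a rolling read could produce. Circles shorter
than half the read length cannot be represented without a second junction
copy and are outside the simulator's default ranges. Linear references
are built strictly within the chosen host transcript: a circle at a
transcript terminus has a declared-absent side, with no fallback to other
transcripts, so linear-junction counts stay host-consistent.

**Matching.** Matching is ungapped. The 2*j* seed must match exactly; up
to *m* mismatches are tolerated elsewhere; `N` on either side is always a
mismatch. The implementation indexes each reference's seed 2*j*-mer and
scans the read's 2*j*-mers, which pins every candidate placement (the
seed must appear in a counted read), so it is exactly equivalent to
sliding the read over every reference — the test suite asserts this
against an exhaustive oracle. Among valid placements the one with fewest
mismatches (ties: smallest offset) is reported. Defaults *j* = 5, *m* = 2,
stranded-forward matching (mate 2 of an FR pair is reverse-complemented
before matching); an unstranded mode tries both orientations.

**Exclusion.** A circular hit is discarded when its read places end-to-end
with ≤ *m* mismatches anywhere in the genome (either strand) or in the
spliced transcriptome. The search uses pigeonhole seeding: any qualifying
placement of a length-*L* read contains an exact *k*-mer with
*k* = ⌊*L*/(*m*+1)⌋, so looking up *m* + 1 disjoint read chunks in a
*k*-mer index finds every placement. Linear-junction hits are not
exclusion-filtered: canonical junction reads are transcriptome-colinear by
construction. *m* is not reported by the original experimental protocol;
2 is this package's default and is recorded in run metadata.

**Counting.** Fragment-level: hits are grouped by fragment id (mates share
a read id), a fragment contributes at most one count per junction, and a
fragment hitting more than one distinct circular junction is dropped as
ambiguous rather than fractionally assigned — conservative and auditable.
The library size used for normalization is the number of input reads with
any ungapped placement (genome, transcriptome or junction references).

**Classification.** Ratios use counts per million placed reads (CPM); a
raw-count mode exists because the normalization choice only matters when
library sizes differ. τ is the nearest-rank (upper) empirical quantile:
exactly ⌈*c·n*⌉ of the *n* linear ratios fall at or below τ, a contract
the tests assert on a cutoff grid. Classification is `ratio > τ` (strict;
ties are conservative and recoverable by rescue) and, being rank-based, is
invariant to monotone transforms applied to all ratios. Candidates not
expressed in mock (below `min_mock`, default 1 read) are not classified.
Diagnostics: a cutoff sweep (true counts per pipeline-support level as a
function of *c*) and within-sample mock-CPM terciles (strictly below the
1/3-quantile is low, strictly above the 2/3-quantile is high, an all-equal
sample is entirely mid). The choice of *c* itself is left to the user.

**Rescue.** The union of per-tissue true lists plus externally validated
lists rescues false calls present in it; provenance (first supporting
tissue or list) is recorded. Rescue only ever grows the true list.

**DE export.** Raw fragment counts with library sizes in a sidecar;
rows with fewer than `min_reads` (default 2) total across the matrix are
dropped. The threshold is interpreted matrix-total by default with a
per-sample switch, since either reading is defensible; the scope used is
recorded in the sidecar. The DE test itself is delegated to external
negative-binomial tools.

## The simulator

The generator emulates the validation experiment, not a sequencer: a toy
genome (default two chromosomes, 120 genes of 2–8 exons, exons 80–250 bp,
introns 60–200 bp, intergenic gaps 200–400 bp, i.i.d. uniform bases); 50
true circles spanning internal exon runs (boundary score 2 by
construction); 50 decoys, half with one or both boundaries shifted 1–10
bases off exon edges (score ≤ 1) and half intergenic (score 0), standing
in statistically for pipeline artifacts; and per-set mock/RNase R FASTQ
libraries. Junction reads (default 60 per junction, 70 bp) start uniformly
at random subject to spanning the junction by at least 5 bases on each
side; linear reads span the host's canonical junctions at the same depth,
so decoy ratios are exchangeable with the linear null. The RNase R library
is a per-read Bernoulli thinning: survival 0.9 for circle junction reads,
0.05 for linear and decoy reads. The optional halving design plants
⌈*r*/2^(s−1)⌉ reads per junction in set *s* (set-1 depth 640 where that
design is exercised). Paired-end mode draws a fragment (default 150 bp)
spanning the junction and emits inward-facing FR mates.

Planted backsplice reads are additionally required to be
junction-diagnostic: a draw whose full sequence places end-to-end on the
genome or transcriptome within the mismatch budget is rejected and
redrawn (up to 60 attempts). Without this, a read with the minimal 5-base
overhang chance-matches its colinear genomic continuation with
probability ≈ 0.1 and is then — correctly — removed by the exclusion
filter, so planted counts could not be recovered exactly. The truth
ledger records every read id exactly once, including per-library
survivors, which is what makes exact-recovery assertions possible.

What the simulator does **not** model: sequencing errors and quality
scores (the method never reads qualities; FASTQ qualities are constant),
PCR duplicates, expression heterogeneity across circles, RNase R
efficiency variation between samples, genomic repeats and homology, and
real pipeline-specific artifact mechanisms (decoys only reproduce their
RNase R sensitivity). Passing tests therefore demonstrate the counting
and classification machinery under clean, well-separated conditions —
they do not by themselves establish performance on real libraries, where
repeat-induced ambiguity and partial RNase R digestion compress the
ratio separation.

## Numerical and design choices

- Deterministic ordering everywhere (sorted candidate keys, sorted
  transcript ids, seeded generators recorded in metadata); identical
  config and inputs give byte-identical outputs.
- Degenerate inputs are defined, not fatal, where a downstream
  interpretation exists: empty FASTQ yields an all-zero table with a
  warning; an empty reference list writes valid empty files; candidates on
  contigs absent from the genome are dropped with a warning. Fatal errors
  are reserved for contract violations: duplicate circ ids, duplicate
  (read, mate) pairs, zero library sizes, a linear ratio sample under 10,
  malformed GTF exons.
- Test problem sizes (8–50 planted circles, tens of reads per junction,
  genomes of ~100 kb) were chosen as the smallest designs at which each
  property is non-vacuous — e.g. the paired-end dedup check uses a 120 bp
  fragment so both 70 bp mates can span one junction, and the halving
  check only evaluates set pairs whose expected totals reach 100 reads.

## Known limitations

- Alternative circRNA isoforms sharing a backsplice junction are summed,
  not resolved; resolving internal exon structure needs full-length
  circle sequencing or a dedicated isoform method.
- Ungapped matching ignores indels; a read with a sequencing indel near
  the junction is lost rather than rescued by gapped alignment.
- The linear null assumes host-gene linear junctions are representative
  of artifact behaviour; strongly structured RNase R-resistant linear
  RNAs violate it and are the known residual false-positive source.
- The exclusion filter removes any read with a plausible linear origin,
  which slightly undercounts circles whose junction context happens to
  resemble the genome within the mismatch budget.
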