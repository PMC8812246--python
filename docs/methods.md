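# Methods

## Detection model

A processed pseudogene is modelled as an intron-less copy of an
annotated multi-exon gene inserted at an arbitrary genomic position,
optionally reverse-complemented, carrying a 3′ poly-A tail and either a
short target-site duplication (TSD) or a small host deletion at the
breakpoints. Detection works entirely from coordinate-addressable
alignments produced by a splice-aware aligner against the ordinary
reference; the copy itself is never assembled.

### Evidence extraction

One pass over the SAM/BAM applies three classifiers to every primary,
non-duplicate alignment with MAPQ ≥ `min_mapq` (default 20):

- **Spliced reads.** Every `N` gap in the CIGAR is matched against the
  exon–exon junction index with ± `slack` bp per boundary (default 0 —
  oracle and STAR-style alignments place junctions exactly). A read
  whose gaps match junctions of several genes is assigned to the gene
  matching the most gaps; ties drop the read. The evidence records the
  *annotated* junction coordinates, so downstream counts key cleanly
  into the index even when slack is nonzero.
- **Chimeric pairs.** A mate overlapping ≥ 1 exonic base of a multi-exon
  gene is chimeric when its partner maps to another chromosome, farther
  than `max_concordant_distance` (default 10 kb), or outside the gene
  locus. The locus test is padded by `locus_pad` (default 500 bp, the
  expected fragment length): without the pad, every concordant pair
  dangling off a terminal exon would be miscalled, and retrocopy-free
  samples would not be evidence-free.
- **Chimeric reads.** A primary alignment with a terminal soft/hard clip
  ≥ `min_clip` (default 20 bp) is chimeric when one side of the split
  (primary or supplementary, from the SA tag) overlaps a multi-exon
  gene's exons and the other maps elsewhere. The breakpoint is the clip
  boundary of the *non-gene* alignment: leftmost aligned base for a
  left clip, one past the rightmost for a right clip. Clipped reads in
  a gene without any supplementary alignment are kept but flagged
  `unanchored`: DNA aligners do not always emit supplementaries, and an
  unanchored clip still corroborates that something interrupts the copy
  — but it carries no usable distal position, so it never seeds or
  joins a cluster.

No read contributes twice to a stream; a pair yields at most one
chimeric-pair record.

### Candidate calling and site resolution

Genes with ≥ `min_sr` spliced reads (default 3) over ≥ `min_junctions`
distinct junctions (default 1) become candidates. For each candidate,
CP distal-mate positions and anchored CR breakpoints — excluding
positions within the parent's own locus ± `window`, which localise
nothing — are sorted and clustered by single linkage with `window`
= 500 bp (the simulated outer distance). In one dimension over sorted
positions single linkage reduces to a chain rule, making the clustering
permutation-invariant and cheap; it is verified against a quadratic
union-find oracle in the tests.

A cluster with CR breakpoints resolves base-precisely to
[min bp, max bp + 1): with a TSD of length *t* the two true breakpoints
are *t* apart, so the called span is *t* + 1 and the TSD length is
recorded as metadata whenever right- and left-clip breakpoints are both
present (a negative offset is recorded as a host deletion instead).
CP-only clusters resolve to a single base at the (lower) median distal
position, flagged approximate with the full cluster span kept as
metadata. Sites are tiered CP-CR / CP / CR by which evidence classes
are present — the tier partition is exhaustive and exclusive by
construction.

Two clusters more than `window` apart are reported as two sites: a
single insertion produces two breakpoints only within a fragment length
of each other, so distant clusters are biologically distinct events.
Candidates with no cluster are still reported (a copy can be detected
even when its location cannot).

### Annotation and orientation

The site *midpoint* (CP-only spans can be wide) is classified against
the gene set: exonic or intronic with the 1-based rank taken from the
canonical transcript, else intergenic. The canonical transcript is the
one with the longest total exonic span, ties broken by smallest
transcript id — the readers ingest only gene/transcript/exon features,
so a CDS-length criterion is not applicable; this rule makes statements
like "intron 18 of the host" deterministic whatever the annotation's
transcript order. When several genes contain the midpoint the smallest
gene span wins, ties alphabetically (logged).

Orientation is a majority vote over stranded evidence. Each record
implies the reference strand of the inserted copy: for a chimeric read
both pieces come from the same sequenced read, so equal gene-side and
distal-side strands mean the copy runs in the parent-aligned direction;
for a chimeric pair the mates are sequenced head-to-head, so the
expectation flips. Composing with the parent strand gives the copy's
reference strand, which is reported relative to the host gene's strand
('+' when intergenic). Ties and strand-less clusters are `unknown`.

### Known-pseudogene annotation

A BED catalog of known processed pseudogenes labels overlapping calls.
A catalog parent name must match the candidate's gene name when
present; by default the parent is derived from the record name by
stripping a trailing `P<digits>` (CBX3P1 → CBX3), with the regex
configurable.

## Coverage QC

Mean per-base depth of primary non-duplicate reads over all target
bases (zeros included — the alternative, covered-bases-only, would
inflate sparse panels). Detection tiers: ≥ 144X confident, ≤ 95X below
detection, gray zone between; both thresholds are config keys. The
downsampler draws mate-paired uniform subsets without replacement,
reproducibly per seed, from FASTQ pairs or by read name from
alignments.

## The simulator

The generator emulates the study conditions end to end:

- **Genome.** Uniform-base chromosomes (default 5 × 100 kb) with
  non-overlapping multi-exon genes (default 20 genes, 3–8 exons of
  100–250 bp, introns 150–600 bp, random strands), written as
  FASTA + GTF. Deterministic per seed.
- **Retrocopy.** Canonical-transcript exons spliced in transcription
  order (reverse-complemented for '−' parents), optional 5′ truncation,
  poly-A appended (default 15 bp; the benchmark draws 10–30 bp).
- **Insertion.** `donor = ref[:pos+tsd] + insert + ref[pos+del:]`, so a
  TSD duplicates `ref[pos:pos+tsd]` on both sides and a deletion removes
  host bases; reverse orientation inserts the reverse complement; an
  optional untemplated spacer models observed unknown insertions at one
  junction. Donor length = reference + copy + TSD − deletion + spacer
  (a tested invariant).
- **Reads.** wgsim-style: uniform fragment starts, *fixed* fragment
  length equal to the 500 bp outer distance (an optional normal jitter
  is off by default — the fixed length makes oracle CIGARs unambiguous),
  mate1 from the fragment 5′ end, mate2 the reverse complement of the
  3′ end, independent per-base substitutions at 2 %, constant qualities,
  no indel errors.
- **Oracle alignments.** Each read's donor interval is projected through
  the donor block map back onto the reference: runs of exon blocks
  become gapped alignments with `N` over the lost introns; reads
  crossing a breakpoint are split, the longest piece becoming the
  primary with terminal soft clips and any other piece ≥ 20 bp emitted
  as a supplementary with reciprocal SA tags; poly-A and spacer bases
  are soft-clipped; pairs straddling the insertion get correct mate
  fields. Pieces shorter than 20 bp are clipped without a supplementary
  — mirroring real aligner anchor limits — and excluded from the
  expected-breakpoint truth.

What the simulator deliberately does **not** model: sequence homology
between genes (every gene is random sequence, so multi-mapping and
MAPQ-0 ambiguity never occur), indel and quality-dependent errors,
chimeric artefacts, and real aligner heuristics. Passing benchmarks
therefore demonstrate the correctness of the evidence logic, clustering
geometry and scoring — not robustness to repetitive genomes, which on
real data is delegated to the aligner's MAPQ and the `min_mapq` filter.

## Benchmarking

Scoring is sample-level because each simulated sample carries one
insertion: a sample is TP if any called site for the true parent gene
overlaps the planted insertion point within the tolerance (default
500 bp, matching the cluster window; the CP-only cluster span counts
toward the overlap), FN otherwise; called sites matching no truth count
as FP; negative controls with no calls count as TN. TPR, PPV,
FDR = 1 − PPV and F1 follow; undefined ratios are reported as NA, never
0. The reference benchmark (100 samples, depth 100X over the simulated
loci, seeds fanned out from one master seed below 2³¹) recovers ≥ 99 %
of insertions with no false positives; residual misses are insertions
that land inside their own parent's locus, where distal evidence is
indistinguishable from the parent and is excluded by design.

Problem sizes used by the shipped checks — 100-sample benchmark,
1000-instance clustering cross-validation, a 70 k-pair sample
downsampled over {1, 5, 10, 25, 50, 70} k pairs on a 50 kb genome —
were chosen to exercise every code path at full read-level realism
while keeping a complete run in the minutes range on one CPU.

## Numerical and degenerate-input choices

- All internal coordinates are 0-based half-open; GTF/SAM conversion
  happens only in readers/writers; displayed coordinates are 1-based
  inclusive; BED stays 0-based.
- Junction sets are unions over transcripts; intron ranks come from the
  canonical transcript.
- Even-sized CP-only clusters take the lower median (deterministic).
- Empty inputs: an empty alignment file yields an empty evidence set;
  an empty catalog leaves all sites novel; an empty target set for
  coverage and an empty gene set for the index are errors.
- Downsampling more pairs than exist is an error naming the available
  count; `n = 0` produces valid empty files.
- The orientation vote returns `unknown` on ties rather than guessing.
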