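"""Extraction of retrocopy evidence from alignments.

A single pass over a SAM/BAM file classifies every primary alignment into
up to three evidence streams:

* spliced reads (SR): reads whose CIGAR carries an N gap exactly matching
  an annotated exon-exon junction — a DNA read can only splice if an
  intron-less gene copy exists somewhere in the sample;
* chimeric pairs (CP): pairs with one mate in a parent gene's exons and
  the other mapping discordantly (other chromosome, beyond the expected
  insert distance, or outside the gene locus) — they localise the
  insertion region;
* chimeric reads (CR): soft-clipped reads whose aligned portion and
  supplementary alignment split between the parent gene and the insertion
  site — they resolve the breakpoint to base precision.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .annotation import JunctionIndex

logger = logging.getLogger("retroscan")

CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_REF_CONSUMING = set("MDN=X")
_READ_CONSUMING = set("MIS=X")


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in CIGAR_RE.findall(cigar)]


def cigar_reference_span(cigar: list[tuple[str, int]]) -> int:
    return sum(n for op, n in cigar if op in _REF_CONSUMING)


def terminal_clips(cigar: list[tuple[str, int]]) -> tuple[int, int]:
    """(left, right) terminal soft/hard clip lengths."""
    left = cigar[0][1] if cigar and cigar[0][0] in "SH" else 0
    right = cigar[-1][1] if cigar and cigar[-1][0] in "SH" else 0
    return left, right


@dataclass(frozen=True)
class SupplementaryTarget:
    chrom: str
    pos: int  # 0-based leftmost
    strand: str
    cigar: tuple[tuple[str, int], ...]

    @property
    def reference_end(self) -> int:
        return self.pos + cigar_reference_span(list(self.cigar))


@dataclass
class AlignedReadView:
    """Aligner-agnostic view of one primary alignment record."""

    read_name: str
    chrom: str
    pos: int
    cigar: list[tuple[str, int]]
    mapq: int
    strand: str
    is_paired: bool
    is_read1: bool
    is_primary: bool
    mate_chrom: str | None
    mate_pos: int | None
    mate_strand: str | None
    supplementary_targets: list[SupplementaryTarget] = field(default_factory=list)
    sequence: str = ""

    @property
    def reference_end(self) -> int:
        return self.pos + cigar_reference_span(self.cigar)

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignedReadView":
        supp = []
        if rec.has_tag("SA"):
            for entry in str(rec.get_tag("SA")).rstrip(";").split(";"):
                chrom, pos, strand, cig, *_ = entry.split(",")
                supp.append(
                    SupplementaryTarget(
                        chrom, int(pos) - 1, strand, tuple(parse_cigar(cig))
                    )
                )
        return cls(
            read_name=rec.query_name,
            chrom=rec.reference_name,
            pos=rec.reference_start,
            cigar=[("MIDNSHP=XB"[op], n) for op, n in (rec.cigartuples or [])],
            mapq=rec.mapping_quality,
            strand="-" if rec.is_reverse else "+",
            is_paired=rec.is_paired,
            is_read1=rec.is_read1 or not rec.is_paired,
            is_primary=not (rec.is_secondary or rec.is_supplementary),
            mate_chrom=rec.next_reference_name if rec.is_paired and not rec.mate_is_unmapped else None,
            mate_pos=rec.next_reference_start if rec.is_paired and not rec.mate_is_unmapped else None,
            mate_strand=("-" if rec.mate_is_reverse else "+")
            if rec.is_paired and not rec.mate_is_unmapped
            else None,
            supplementary_targets=supp,
            sequence=rec.query_sequence or "",
        )


# ---------------------------------------------------------------------------
# evidence records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SplicedReadEvidence:
    read_name: str
    gene_id: str
    junctions_matched: tuple[tuple[int, int, int], ...]  # (donor, acceptor, intron_rank)
    mapq: int


@dataclass(frozen=True)
class ChimericPairEvidence:
    read_name: str
    gene_id: str
    gene_mate: tuple[str, int, str]  # chrom, pos, strand of the exon-overlapping mate
    distal_mate: tuple[str, int, str]
    mapq_min: int


@dataclass(frozen=True)
class ChimericReadEvidence:
    read_name: str
    gene_id: str
    breakpoint: tuple[str, int]  # clip boundary on the distal (non-gene) side
    clip_side: str  # 'left' | 'right', on the distal-side alignment
    clip_len: int
    gene_side: tuple[str, int, str]
    distal_strand: str
    unanchored: bool = False


@dataclass
class EvidenceSet:
    """All evidence collected from one sample's alignments."""

    spliced: list[SplicedReadEvidence] = field(default_factory=list)
    pairs: list[ChimericPairEvidence] = field(default_factory=list)
    clips: list[ChimericReadEvidence] = field(default_factory=list)
    junction_sr_counts: dict[tuple[str, int, int], int] = field(default_factory=dict)
    reads_seen: int = 0
    reads_filtered: int = 0

    def sr_by_gene(self) -> dict[str, list[SplicedReadEvidence]]:
        out: dict[str, list[SplicedReadEvidence]] = {}
        for ev in self.spliced:
            out.setdefault(ev.gene_id, []).append(ev)
        return out


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


def _n_gaps(view: AlignedReadView) -> list[tuple[int, int]]:
    """(donor, acceptor) of every N gap, donor = first skipped base."""
    gaps = []
    ref = view.pos
    for op, n in view.cigar:
        if op == "N":
            gaps.append((ref, ref + n))
        if op in _REF_CONSUMING:
            ref += n
    return gaps


def match_spliced_read(
    view: AlignedReadView, index: JunctionIndex, slack: int = 0
) -> SplicedReadEvidence | None:
    """Match a read's N gaps against annotated junctions.

    Gaps matching junctions of several genes are resolved to the gene
    matching the most gaps; a tie drops the read (logged).
    """
    if not view.is_primary:
        return None
    per_gene: dict[str, list[tuple[int, int, int]]] = {}
    for donor, acceptor in _n_gaps(view):
        for gene_id, rank, jd, ja in index.match_junction_full(
            view.chrom, donor, acceptor, slack
        ):
            per_gene.setdefault(gene_id, []).append((jd, ja, rank))
    if not per_gene:
        return None
    best = max(len(v) for v in per_gene.values())
    winners = sorted(g for g, v in per_gene.items() if len(v) == best)
    if len(winners) > 1:
        logger.debug(
            "read %s matches junctions of %d genes equally, dropped",
            view.read_name,
            len(winners),
        )
        return None
    gene_id = winners[0]
    return SplicedReadEvidence(
        read_name=view.read_name,
        gene_id=gene_id,
        junctions_matched=tuple(sorted(set(per_gene[gene_id]))),
        mapq=view.mapq,
    )


def classify_chimeric_pair(
    view: AlignedReadView,
    index: JunctionIndex,
    max_concordant_distance: int = 10_000,
    locus_pad: int = 500,
) -> ChimericPairEvidence | None:
    """Chimeric-pair test for the exon-overlapping mate of a pair.

    The pair is discordant if the mate maps to another chromosome, beyond
    ``max_concordant_distance``, or outside the gene's locus span.  The
    locus is padded by ``locus_pad`` (the expected fragment length) so
    concordant pairs dangling off a terminal exon are not miscalled.
    """
    if not (view.is_paired and view.is_primary and view.mate_chrom is not None):
        return None
    gene_ids = index.exon_overlap_genes(view.chrom, view.pos, view.reference_end)
    if not gene_ids:
        return None
    for gene_id in gene_ids:
        chrom, lo, hi = index.locus(gene_id)
        discordant = (
            view.mate_chrom != view.chrom
            or abs(view.mate_pos - view.pos) > max_concordant_distance
            or not (lo - locus_pad <= view.mate_pos < hi + locus_pad)
        )
        if discordant:
            return ChimericPairEvidence(
                read_name=view.read_name,
                gene_id=gene_id,
                gene_mate=(view.chrom, view.pos, view.strand),
                distal_mate=(view.mate_chrom, view.mate_pos, view.mate_strand),
                mapq_min=view.mapq,
            )
    return None


def _supp_overlaps_exons(supp: SupplementaryTarget, index: JunctionIndex) -> list[str]:
    return index.exon_overlap_genes(supp.chrom, supp.pos, supp.reference_end)


def _clip_boundary(
    chrom: str, pos: int, ref_end: int, cigar: list[tuple[str, int]]
) -> tuple[tuple[str, int], str, int] | None:
    """Breakpoint implied by the larger terminal clip of an alignment:
    a left clip points at the leftmost aligned base, a right clip one past
    the rightmost.  Returns ((chrom, pos), side, clip_len)."""
    left, right = terminal_clips(cigar)
    if left == 0 and right == 0:
        return None
    if left >= right:
        return (chrom, pos), "left", left
    return (chrom, ref_end), "right", right


def extract_chimeric_read(
    view: AlignedReadView, index: JunctionIndex, min_clip: int = 20
) -> ChimericReadEvidence | None:
    """Soft-clipped read splitting between a parent gene and a distal site.

    The breakpoint is taken from the clip boundary of the alignment on the
    non-gene (insertion) side.  When the primary sits in the gene and no
    supplementary alignment is available the record is flagged
    ``unanchored``: its breakpoint is on the gene side only and it can
    merely corroborate a chimeric-pair cluster.
    """
    if not view.is_primary:
        return None
    left, right = terminal_clips(view.cigar)
    if max(left, right) < min_clip:
        return None
    primary_genes = index.exon_overlap_genes(view.chrom, view.pos, view.reference_end)

    if primary_genes:
        gene_id = primary_genes[0]
        gene_side = (view.chrom, view.pos, view.strand)
        for supp in view.supplementary_targets:
            if gene_id in _supp_overlaps_exons(supp, index):
                continue  # both sides in the same gene: not an insertion split
            bp = _clip_boundary(
                supp.chrom, supp.pos, supp.reference_end, list(supp.cigar)
            )
            if bp is None:
                continue
            (bchrom, bpos), side, clip_len = bp
            return ChimericReadEvidence(
                read_name=view.read_name,
                gene_id=gene_id,
                breakpoint=(bchrom, bpos),
                clip_side=side,
                clip_len=max(left, right),
                gene_side=gene_side,
                distal_strand=supp.strand,
                unanchored=False,
            )
        # clipped in the gene with no usable supplementary target
        bp = _clip_boundary(view.chrom, view.pos, view.reference_end, view.cigar)
        (bchrom, bpos), side, clip_len = bp
        return ChimericReadEvidence(
            read_name=view.read_name,
            gene_id=gene_id,
            breakpoint=(bchrom, bpos),
            clip_side=side,
            clip_len=clip_len,
            gene_side=gene_side,
            distal_strand=view.strand,
            unanchored=True,
        )

    # primary on the distal side; gene membership must come from a supplementary
    for supp in view.supplementary_targets:
        genes = _supp_overlaps_exons(supp, index)
        if not genes:
            continue
        bp = _clip_boundary(view.chrom, view.pos, view.reference_end, view.cigar)
        if bp is None:
            return None
        (bchrom, bpos), side, clip_len = bp
        return ChimericReadEvidence(
            read_name=view.read_name,
            gene_id=genes[0],
            breakpoint=(bchrom, bpos),
            clip_side=side,
            clip_len=clip_len,
            gene_side=(supp.chrom, supp.pos, supp.strand),
            distal_strand=view.strand,
            unanchored=False,
        )
    return None


# ---------------------------------------------------------------------------
# the single-pass scanner
# ---------------------------------------------------------------------------


@dataclass
class ScanParams:
    min_mapq: int = 20
    slack: int = 0
    max_concordant_distance: int = 10_000
    min_clip: int = 20
    locus_pad: int = 500  # expected fragment length around a gene locus


def scan_alignments(
    path: str | Path, index: JunctionIndex, params: ScanParams | None = None
) -> EvidenceSet:
    """Single pass over a SAM/BAM file applying the three classifiers.

    Secondary, supplementary and duplicate-marked records are skipped, as
    are records below ``min_mapq``.  No read contributes twice to the same
    stream; a pair contributes at most one chimeric-pair record.
    """
    params = params or ScanParams()
    ev = EvidenceSet()
    sr_seen: set[tuple[str, bool]] = set()
    cp_seen: set[str] = set()
    cr_seen: set[tuple[str, bool]] = set()
    known_chroms = {g.chrom for g in index.genes.values()}
    warned_chroms: set[str] = set()

    with pysam.AlignmentFile(str(path), check_sq=False) as aln:
        for rec in aln:
            ev.reads_seen += 1
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                ev.reads_filtered += 1
                continue
            if rec.mapping_quality < params.min_mapq:
                ev.reads_filtered += 1
                continue
            view = AlignedReadView.from_pysam(rec)
            if view.chrom not in known_chroms and view.chrom not in warned_chroms:
                logger.warning(
                    "chromosome %s absent from the annotation; reads on it are "
                    "still usable as distal coordinates",
                    view.chrom,
                )
                warned_chroms.add(view.chrom)

            key = (view.read_name, view.is_read1)
            sr = match_spliced_read(view, index, params.slack)
            if sr is not None and key not in sr_seen:
                sr_seen.add(key)
                ev.spliced.append(sr)
                for donor, acceptor, _rank in sr.junctions_matched:
                    jkey = (view.chrom, donor, acceptor)
                    ev.junction_sr_counts[jkey] = ev.junction_sr_counts.get(jkey, 0) + 1

            cp = classify_chimeric_pair(
                view, index, params.max_concordant_distance, params.locus_pad
            )
            if cp is not None and view.read_name not in cp_seen:
                cp_seen.add(view.read_name)
                ev.pairs.append(cp)

            cr = extract_chimeric_read(view, index, params.min_clip)
            if cr is not None and key not in cr_seen:
                cr_seen.add(key)
                ev.clips.append(cr)
    return ev
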