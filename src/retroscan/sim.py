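"""Truth-tracked retrocopy simulator.

Generates everything the detection pipeline consumes, with no external
data: toy genomes and annotations, retrocopy sequences (introns removed,
3' poly-A tail, optional 5' truncation), donor genomes carrying the
insertion with its breakpoint micro-features (target-site duplication,
small host deletion, unknown spacer sequence, reverse orientation),
wgsim-style paired-end reads, and *oracle alignments*: the SAM records a
correct splice-aware aligner would produce against the pre-insertion
reference — N gaps over lost introns, terminal soft clips at breakpoints
with supplementary-alignment (SA) annotations, and discordant mate
placement for pairs straddling the insertion.

Every planted insertion and its realized breakpoints are recorded in a
truth manifest for benchmarking.

Defaults mirror the simulated study conditions: 90 bp reads, 500 bp outer
distance, 2% substitution error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .annotation import GeneModel, Genome, reverse_complement, write_fasta, write_gtf

logger = logging.getLogger("retroscan")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# specs and truth records
# ---------------------------------------------------------------------------


@dataclass
class RetrocopySpec:
    """One retrocopy insertion to plant in a donor genome."""

    parent_gene_id: str
    target_chrom: str
    target_pos: int  # 0-based insertion point on the reference
    orientation: str = "forward"  # mRNA direction along the host '+' strand
    polyA_len: int = 15
    tsd_len: int = 4
    five_prime_truncation: int = 0
    breakpoint_deletion: int = 0
    spacer: str = ""  # extra untemplated sequence at the 3' junction

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.polyA_len < 0 or self.tsd_len < 0 or self.breakpoint_deletion < 0:
            raise ValueError("lengths must be non-negative")
        if self.tsd_len > 0 and self.breakpoint_deletion > 0:
            raise ValueError("tsd_len and breakpoint_deletion cannot both be > 0")


@dataclass
class ReadSimParams:
    """wgsim-style paired-end read simulation parameters."""

    read_len: int = 90
    outer_distance: int = 500  # fixed fragment (outer) length
    error_rate: float = 0.02  # independent per-base substitution probability
    frag_sd: int = 0  # optional normal jitter on the fragment length

    def __post_init__(self) -> None:
        if not self.read_len < self.outer_distance:
            raise ValueError("read_len must be < outer_distance")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class PlacedRetrocopy:
    """Truth record for one planted insertion (reference coordinates)."""

    sample_id: str
    parent_gene_id: str
    parent_gene_name: str
    chrom: str
    pos: int  # insertion point
    tsd_len: int
    polyA_len: int
    orientation: str
    truncation: int
    deletion: int
    spacer_len: int
    retro_len: int  # mRNA + polyA length
    bp_left: int  # reference coord where the upstream host segment ends
    bp_right: int  # reference coord where the downstream host segment resumes
    insert_start: int = 0  # donor coordinate where the insert begins
    insert_end: int = 0

    MANIFEST_COLUMNS = (
        "sample_id parent_gene_id parent_gene_name chrom pos tsd_len polyA_len "
        "orientation truncation deletion spacer_len retro_len bp_left bp_right "
        "insert_start insert_end"
    ).split()


@dataclass
class TruthManifest:
    """Simulator ground truth: one entry per planted insertion.

    Negative-control samples appear with an entry whose ``parent_gene_id``
    is empty, so the scorer can count true negatives.
    """

    entries: list[PlacedRetrocopy] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        cols = PlacedRetrocopy.MANIFEST_COLUMNS
        with open(path, "w") as out:
            out.write("\t".join(cols) + "\n")
            for e in self.entries:
                out.write("\t".join(str(getattr(e, c)) for c in cols) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthManifest":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                vals = dict(zip(header, line.rstrip("\n").split("\t")))
                entries.append(
                    PlacedRetrocopy(
                        sample_id=vals["sample_id"],
                        parent_gene_id=vals["parent_gene_id"],
                        parent_gene_name=vals["parent_gene_name"],
                        chrom=vals["chrom"],
                        pos=int(vals["pos"]),
                        tsd_len=int(vals["tsd_len"]),
                        polyA_len=int(vals["polyA_len"]),
                        orientation=vals["orientation"],
                        truncation=int(vals["truncation"]),
                        deletion=int(vals["deletion"]),
                        spacer_len=int(vals["spacer_len"]),
                        retro_len=int(vals["retro_len"]),
                        bp_left=int(vals["bp_left"]),
                        bp_right=int(vals["bp_right"]),
                        insert_start=int(vals["insert_start"]),
                        insert_end=int(vals["insert_end"]),
                    )
                )
        return cls(entries)


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def generate_genome(
    n_chroms: int = 5,
    chrom_len: int = 100_000,
    n_genes: int = 20,
    exons_per_gene_range: tuple[int, int] = (3, 8),
    seed: int = 0,
    exon_len_range: tuple[int, int] = (100, 250),
    intron_len_range: tuple[int, int] = (150, 600),
    margin: int = 2_000,
    out_fasta: str | Path | None = None,
    out_gtf: str | Path | None = None,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random reference: uniform-base chromosomes with non-overlapping
    multi-exon genes on random strands.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    seqs = {f"chr{i + 1}": _random_seq(rng, chrom_len) for i in range(n_chroms)}
    chrom_names = list(seqs)
    cursors = {c: margin for c in chrom_names}
    genes: list[GeneModel] = []
    for gi in range(n_genes):
        chrom = chrom_names[gi % n_chroms]
        n_exons = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
        exon_lens = rng.integers(exon_len_range[0], exon_len_range[1] + 1, n_exons)
        intron_lens = rng.integers(
            intron_len_range[0], intron_len_range[1] + 1, max(n_exons - 1, 0)
        )
        span = int(exon_lens.sum() + intron_lens.sum())
        start = cursors[chrom] + int(rng.integers(500, 3_000))
        if start + span > chrom_len - margin:
            raise ValueError(
                f"cannot place gene {gi + 1}/{n_genes}: chromosome {chrom} is full "
                f"(need {span} bp at {start}, length {chrom_len})"
            )
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        cursors[chrom] = pos
        strand = "+" if rng.random() < 0.5 else "-"
        from .annotation import make_gene

        genes.append(make_gene(f"G{gi + 1:03d}", chrom, strand, exons))
    if out_fasta is not None:
        write_fasta(seqs, out_fasta)
    if out_gtf is not None:
        write_gtf(genes, out_gtf)
    return seqs, genes


# ---------------------------------------------------------------------------
# retrocopy construction and insertion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Block:
    """One segment of donor sequence and where it came from.

    Aligned blocks (``host``/``exon``) map to reference coordinates;
    strand '-' means donor offset *i* within the block corresponds to the
    complement of reference position ``ref_end - 1 - i``.  ``polyA`` and
    ``spacer`` blocks have no reference origin.
    """

    length: int
    kind: str  # 'host' | 'exon' | 'polyA' | 'spacer'
    chrom: str | None = None
    ref_start: int | None = None
    ref_end: int | None = None
    strand: str = "+"
    gene_id: str | None = None

    @property
    def aligned(self) -> bool:
        return self.kind in ("host", "exon")


def build_retrocopy(parent: GeneModel, genome: Genome, spec: RetrocopySpec) -> str:
    """Processed-mRNA sequence of the parent gene: exons spliced together
    in transcription order, 5'-truncated, with a poly-A tail appended."""
    exons = parent.canonical_transcript.exons
    if parent.strand == "+":
        mrna = "".join(genome.fetch(parent.chrom, e.start, e.end) for e in exons)
    else:
        mrna = reverse_complement(
            "".join(genome.fetch(parent.chrom, e.start, e.end) for e in exons)
        )
    if spec.five_prime_truncation >= len(mrna):
        raise ValueError(
            f"truncation {spec.five_prime_truncation} >= mRNA length {len(mrna)}"
        )
    return mrna[spec.five_prime_truncation :] + "A" * spec.polyA_len


def _retro_blocks(parent: GeneModel, spec: RetrocopySpec) -> list[Block]:
    """Blocks of the mRNA+polyA in mRNA (5'->3') order."""
    exons = parent.canonical_transcript.exons
    blocks: list[Block] = []
    ordered = exons if parent.strand == "+" else list(reversed(exons))
    for e in ordered:
        blocks.append(
            Block(
                length=len(e),
                kind="exon",
                chrom=parent.chrom,
                ref_start=e.start,
                ref_end=e.end,
                strand=parent.strand,
                gene_id=parent.gene_id,
            )
        )
    # 5' truncation trims from the mRNA front
    trim = spec.five_prime_truncation
    while trim > 0 and blocks:
        b = blocks[0]
        if trim >= b.length:
            trim -= b.length
            blocks.pop(0)
        else:
            if b.strand == "+":
                blocks[0] = replace(b, length=b.length - trim, ref_start=b.ref_start + trim)
            else:
                blocks[0] = replace(b, length=b.length - trim, ref_end=b.ref_end - trim)
            trim = 0
    if spec.polyA_len > 0:
        blocks.append(Block(length=spec.polyA_len, kind="polyA"))
    return blocks


def _flip_block(b: Block) -> Block:
    if not b.aligned:
        return b
    return replace(b, strand="-" if b.strand == "+" else "+")


class DonorMap:
    """Donor-chromosome coordinate map: ordered blocks with cumulative
    offsets, supporting projection of donor intervals onto the reference."""

    def __init__(self, blocks: list[Block]):
        self.blocks = blocks
        self.offsets = np.cumsum([0] + [b.length for b in blocks])

    @property
    def length(self) -> int:
        return int(self.offsets[-1])

    def project(self, start: int, end: int) -> list["Piece"]:
        """Split donor interval [start, end) at block boundaries.

        Each piece carries its offset within the interval and, for aligned
        blocks, its reference sub-interval.
        """
        pieces: list[Piece] = []
        i = int(np.searchsorted(self.offsets, start, side="right")) - 1
        pos = start
        while pos < end and i < len(self.blocks):
            b = self.blocks[i]
            b_start, b_end = int(self.offsets[i]), int(self.offsets[i + 1])
            lo, hi = max(pos, b_start), min(end, b_end)
            if lo < hi:
                if b.aligned:
                    if b.strand == "+":
                        rs = b.ref_start + (lo - b_start)
                        re_ = b.ref_start + (hi - b_start)
                    else:
                        rs = b.ref_end - (hi - b_start)
                        re_ = b.ref_end - (lo - b_start)
                    pieces.append(
                        Piece(lo - start, hi - start, True, b.chrom, rs, re_, b.strand, b.kind, b.gene_id)
                    )
                else:
                    pieces.append(
                        Piece(lo - start, hi - start, False, None, None, None, "+", b.kind, None)
                    )
            pos = hi
            i += 1
        return pieces


@dataclass(frozen=True)
class Piece:
    off_start: int  # offsets within the projected interval
    off_end: int
    aligned: bool
    chrom: str | None
    ref_start: int | None
    ref_end: int | None
    strand: str
    kind: str
    gene_id: str | None

    @property
    def length(self) -> int:
        return self.off_end - self.off_start


def insert_retrocopy(
    ref_seqs: dict[str, str],
    retro_seq: str,
    spec: RetrocopySpec,
    parent: GeneModel,
    sample_id: str = "sample",
) -> tuple[dict[str, str], dict[str, DonorMap], PlacedRetrocopy]:
    """Plant a retrocopy in the reference, producing the donor genome,
    its coordinate maps and the truth record.

    With a target-site duplication of length *t* the host bases
    ``[pos, pos+t)`` appear on both sides of the insert; with a breakpoint
    deletion of length *d* the host loses ``[pos, pos+d)``.
    """
    chrom = spec.target_chrom
    ref = ref_seqs[chrom]
    pos, tsd, dele = spec.target_pos, spec.tsd_len, spec.breakpoint_deletion
    if pos < 0 or pos + tsd > len(ref) or pos + dele > len(ref):
        raise ValueError(f"insertion at {chrom}:{pos} out of range")
    oriented = retro_seq if spec.orientation == "forward" else reverse_complement(retro_seq)
    insert = oriented + spec.spacer
    donor = dict(ref_seqs)
    donor[chrom] = ref[: pos + tsd] + insert + ref[pos + dele :]

    rblocks = _retro_blocks(parent, spec)
    if spec.orientation == "reverse":
        rblocks = [_flip_block(b) for b in reversed(rblocks)]
    if spec.spacer:
        rblocks.append(Block(length=len(spec.spacer), kind="spacer"))
    blocks = []
    if pos + tsd > 0:
        blocks.append(Block(pos + tsd, "host", chrom, 0, pos + tsd, "+"))
    blocks.extend(rblocks)
    if pos + dele < len(ref):
        blocks.append(Block(len(ref) - pos - dele, "host", chrom, pos + dele, len(ref), "+"))

    maps = {
        c: DonorMap([Block(len(s), "host", c, 0, len(s), "+")])
        for c, s in ref_seqs.items()
    }
    maps[chrom] = DonorMap(blocks)

    placed = PlacedRetrocopy(
        sample_id=sample_id,
        parent_gene_id=parent.gene_id,
        parent_gene_name=parent.gene_name,
        chrom=chrom,
        pos=pos,
        tsd_len=tsd,
        polyA_len=spec.polyA_len,
        orientation=spec.orientation,
        truncation=spec.five_prime_truncation,
        deletion=dele,
        spacer_len=len(spec.spacer),
        retro_len=len(retro_seq),
        bp_left=pos + tsd,
        bp_right=pos + dele,
        insert_start=pos + tsd,
        insert_end=pos + tsd + len(insert),
    )
    return donor, maps, placed


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class ReadPair:
    name: str
    chrom: str  # donor chromosome
    frag_start: int  # donor coordinates
    frag_end: int
    seq1: str  # as sequenced (mate1 = fragment 5', donor-forward)
    seq2: str  # as sequenced (mate2 = revcomp of fragment 3')

    @property
    def mate1_interval(self) -> tuple[int, int]:
        return self.frag_start, self.frag_start + len(self.seq1)

    @property
    def mate2_interval(self) -> tuple[int, int]:
        return self.frag_end - len(self.seq2), self.frag_end


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(len(arr)) < error_rate
    if mask.any():
        idx = np.flatnonzero(mask)
        codes = np.searchsorted(_BASES, arr[idx])  # ACGT are sorted
        arr[idx] = _BASES[(codes + rng.integers(1, 4, idx.size)) % 4]
    return arr.tobytes().decode()


def simulate_reads(
    donor: dict[str, str],
    params: ReadSimParams,
    n_pairs: int,
    rng: np.random.Generator,
    region: tuple[str, int, int] | None = None,
    name_prefix: str = "frag",
) -> list[ReadPair]:
    """Uniform fragment starts over ``region`` (default: the first donor
    chromosome), fixed fragment length = outer_distance (optionally
    jittered), mate1 from the fragment 5' end, mate2 the reverse
    complement of the 3' end, independent substitution errors."""
    if region is None:
        chrom = next(iter(donor))
        region = (chrom, 0, len(donor[chrom]))
    chrom, lo, hi = region
    seq = donor[chrom]
    hi = min(hi, len(seq))
    pairs: list[ReadPair] = []
    span = hi - lo - params.outer_distance
    if span <= 0:
        raise ValueError("region shorter than the outer distance")
    starts = rng.integers(lo, lo + span + 1, n_pairs)
    if params.frag_sd > 0:
        lens = np.maximum(
            params.read_len + 1,
            np.round(rng.normal(params.outer_distance, params.frag_sd, n_pairs)).astype(int),
        )
    else:
        lens = np.full(n_pairs, params.outer_distance)
    for i in range(n_pairs):
        s = int(starts[i])
        e = min(s + int(lens[i]), len(seq))
        frag = seq[s:e]
        m1 = frag[: params.read_len]
        m2 = reverse_complement(frag[-params.read_len :])
        pairs.append(
            ReadPair(
                name=f"{name_prefix}{i:06d}",
                chrom=chrom,
                frag_start=s,
                frag_end=e,
                seq1=_mutate(m1, rng, params.error_rate),
                seq2=_mutate(m2, rng, params.error_rate),
            )
        )
    return pairs


def write_fastq(pairs: list[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            q2 = "I" * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# oracle alignment writer
# ---------------------------------------------------------------------------


@dataclass
class _LocalAln:
    """One gapped local alignment of a (donor-forward) read sub-interval."""

    read_start: int  # offsets in donor-forward read coordinates
    read_end: int
    chrom: str
    strand: str  # of the underlying donor blocks vs the reference
    pieces: list[Piece]

    @property
    def aligned_len(self) -> int:
        return self.read_end - self.read_start

    def sam_geometry(self, read_len: int) -> tuple[int, str]:
        """(0-based POS, CIGAR) in SAM (reference-forward) orientation."""
        if self.strand == "+":
            ordered = self.pieces
        else:
            ordered = list(reversed(self.pieces))
        pos = ordered[0].ref_start
        ops = []
        left = self.read_start if self.strand == "+" else read_len - self.read_end
        right = read_len - self.read_end if self.strand == "+" else self.read_start
        if left:
            ops.append(f"{left}S")
        for i, piece in enumerate(ordered):
            if i > 0:
                gap = piece.ref_start - ordered[i - 1].ref_end
                ops.append(f"{gap}N")
            ops.append(f"{piece.length}M")
        if right:
            ops.append(f"{right}S")
        return pos, "".join(ops)


def _merge_pieces(pieces: list[Piece]) -> list[_LocalAln]:
    runs: list[_LocalAln] = []
    for piece in pieces:
        if not piece.aligned:
            continue
        if (
            runs
            and piece.kind == "exon"
            and runs[-1].pieces[-1].kind == "exon"
            and runs[-1].pieces[-1].gene_id == piece.gene_id
            and runs[-1].strand == piece.strand
            and runs[-1].read_end == piece.off_start
        ):
            runs[-1].pieces.append(piece)
            runs[-1].read_end = piece.off_end
        else:
            runs.append(
                _LocalAln(piece.off_start, piece.off_end, piece.chrom, piece.strand, [piece])
            )
    return runs


@dataclass
class OracleRecord:
    name: str
    flag: int
    chrom: str | None
    pos: int
    mapq: int
    cigar: str
    seq: str
    mate_chrom: str | None = None
    mate_pos: int = -1
    sa: str | None = None


@dataclass
class MateTruth:
    """True alignment anatomy of one simulated mate."""

    name: str
    mate: int
    junctions: list[tuple[str, int, int]] = field(default_factory=list)
    split: bool = False
    breakpoints: list[tuple[str, int]] = field(default_factory=list)
    mapped: bool = True


def _project_mate(
    name: str,
    mate: int,
    interval: tuple[int, int],
    seq: str,
    donor_map: DonorMap,
    min_anchor: int,
) -> tuple[list[OracleRecord], MateTruth]:
    s, e = interval
    read_len = e - s
    mate_strand = "+" if mate == 1 else "-"
    fwd_seq = seq if mate == 1 else reverse_complement(seq)
    pieces = donor_map.project(s, e)
    runs = _merge_pieces(pieces)
    truth = MateTruth(name=name, mate=mate)
    if not runs:
        truth.mapped = False
        return (
            [OracleRecord(name, 0x1 | 0x4 | (0x40 if mate == 1 else 0x80), None, -1, 0, "*", seq)],
            truth,
        )
    primary = max(runs, key=lambda r: r.aligned_len)
    emitted = [primary] + [
        r for r in runs if r is not primary and r.aligned_len >= min_anchor
    ]
    truth.split = len(emitted) > 1
    for r in emitted:
        for i in range(1, len(r.pieces)):
            a, b = (r.pieces[i - 1], r.pieces[i]) if r.strand == "+" else (
                r.pieces[i], r.pieces[i - 1]
            )
            truth.junctions.append((r.chrom, a.ref_end, b.ref_start))
    if truth.split:
        # true breakpoints: the boundary of each host-side run facing the
        # insert (host runs are single pieces on the '+' strand)
        for r in emitted:
            p0 = r.pieces[0]
            if p0.kind != "host":
                continue
            if r.read_start > 0:  # insert lies 5' of this run in donor coords
                bp = p0.ref_start
            else:
                bp = p0.ref_end
            truth.breakpoints.append((r.chrom, bp))

    records = []
    sa_parts = []
    for r in emitted:
        pos, cig = r.sam_geometry(read_len)
        strand = "+" if mate_strand == r.strand else "-"
        sa_parts.append(f"{r.chrom},{pos + 1},{strand},{cig},60,0")
    for idx, r in enumerate(emitted):
        pos, cig = r.sam_geometry(read_len)
        reverse = mate_strand != r.strand
        flag = 0x1 | (0x40 if mate == 1 else 0x80)
        if reverse:
            flag |= 0x10
        if idx > 0:
            flag |= 0x800
        sa = None
        if len(emitted) > 1:
            sa = ";".join(sa_parts[:idx] + sa_parts[idx + 1 :]) + ";"
        records.append(
            OracleRecord(
                name=name,
                flag=flag,
                chrom=r.chrom,
                pos=pos,
                mapq=60,
                cigar=cig,
                seq=fwd_seq if r.strand == "+" else reverse_complement(fwd_seq),
                sa=sa,
            )
        )
    return records, truth


def oracle_alignments(
    pairs: list[ReadPair],
    donor_maps: dict[str, DonorMap],
    min_anchor: int = 20,
) -> tuple[list[OracleRecord], list[MateTruth]]:
    """Project simulated reads back onto the reference as an ideal
    splice-aware aligner would report them."""
    records: list[OracleRecord] = []
    truths: list[MateTruth] = []
    for p in pairs:
        dm = donor_maps[p.chrom]
        rec1, t1 = _project_mate(p.name, 1, p.mate1_interval, p.seq1, dm, min_anchor)
        rec2, t2 = _project_mate(p.name, 2, p.mate2_interval, p.seq2, dm, min_anchor)
        # cross-fill mate fields from each mate's primary record
        pri1, pri2 = rec1[0], rec2[0]
        for r in rec1:
            r.mate_chrom, r.mate_pos = pri2.chrom, pri2.pos
            if pri2.flag & 0x10:
                r.flag |= 0x20
            if pri2.flag & 0x4:
                r.flag |= 0x8
        for r in rec2:
            r.mate_chrom, r.mate_pos = pri1.chrom, pri1.pos
            if pri1.flag & 0x10:
                r.flag |= 0x20
            if pri1.flag & 0x4:
                r.flag |= 0x8
        records.extend(rec1)
        records.extend(rec2)
        truths.extend([t1, t2])
    return records, truths


def write_oracle_alignments(
    pairs: list[ReadPair],
    donor_maps: dict[str, DonorMap],
    ref_lengths: dict[str, int],
    path: str | Path,
    min_anchor: int = 20,
) -> list[MateTruth]:
    """Write coordinate-sorted oracle SAM for the given reads; returns the
    per-mate truth records."""
    records, truths = oracle_alignments(pairs, donor_maps, min_anchor)
    chrom_order = {c: i for i, c in enumerate(ref_lengths)}
    records.sort(
        key=lambda r: (r.chrom is None, chrom_order.get(r.chrom, 1 << 30), r.pos, r.name)
    )
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.flag = r.flag
            if r.chrom is not None:
                a.reference_id = out.header.get_tid(r.chrom)
                a.reference_start = r.pos
                a.mapping_quality = r.mapq
                a.cigarstring = r.cigar
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array("I" * len(r.seq))
            if r.mate_chrom is not None:
                a.next_reference_id = out.header.get_tid(r.mate_chrom)
                a.next_reference_start = r.mate_pos
            if r.sa:
                a.set_tag("SA", r.sa)
            out.write(a)
    return truths


# ---------------------------------------------------------------------------
# per-sample orchestration
# ---------------------------------------------------------------------------


@dataclass
class SampleSim:
    sample_id: str
    truth: PlacedRetrocopy | None
    pairs: list[ReadPair]
    sam_path: Path
    read_truths: list[MateTruth]


def simulate_sample(
    ref_seqs: dict[str, str],
    genes: list[GeneModel],
    spec: RetrocopySpec | None,
    read_params: ReadSimParams,
    depth: float,
    seed: int,
    out_sam: str | Path,
    sample_id: str = "sample",
    region_pad: int = 700,
    parent_depth: float | None = None,
    min_anchor: int = 20,
) -> SampleSim:
    """Simulate one sample: donor construction, reads over the insertion
    neighbourhood (plus concordant coverage over the parent locus), and
    oracle alignments.

    ``depth`` is the target mean coverage over the simulated window(s).
    A ``spec`` of None produces a negative-control sample: concordant
    reads over a gene locus of the unmodified reference.
    """
    rng = np.random.default_rng(seed)
    gene_by_id = {g.gene_id: g for g in genes}
    ref_lengths = {c: len(s) for c, s in ref_seqs.items()}

    def n_pairs_for(window: int, d: float) -> int:
        return max(1, int(round(d * window / (2 * read_params.read_len))))

    if spec is None:
        gene = genes[int(rng.integers(0, len(genes)))]
        lo, hi = gene.locus
        region = (gene.chrom, max(0, lo - region_pad), min(ref_lengths[gene.chrom], hi + region_pad))
        donor = dict(ref_seqs)
        maps = {
            c: DonorMap([Block(len(s), "host", c, 0, len(s), "+")])
            for c, s in ref_seqs.items()
        }
        placed = None
        pairs = simulate_reads(
            donor,
            read_params,
            n_pairs_for(region[2] - region[1], depth),
            rng,
            region=region,
            name_prefix=f"{sample_id}.bg",
        )
    else:
        parent = gene_by_id[spec.parent_gene_id]
        genome = Genome(ref_seqs)
        retro = build_retrocopy(parent, genome, spec)
        donor, maps, placed = insert_retrocopy(ref_seqs, retro, spec, parent, sample_id)
        lo = max(0, placed.insert_start - region_pad)
        hi = min(len(donor[spec.target_chrom]), placed.insert_end + region_pad)
        pairs = simulate_reads(
            donor,
            read_params,
            n_pairs_for(hi - lo, depth),
            rng,
            region=(spec.target_chrom, lo, hi),
            name_prefix=f"{sample_id}.ins",
        )
        pd = depth if parent_depth is None else parent_depth
        if pd > 0:
            glo, ghi = parent.locus
            # donor coordinates of the parent locus: unchanged unless the
            # insertion chrom precedes it on the same chromosome
            shift = 0
            if parent.chrom == spec.target_chrom and placed.pos <= glo:
                shift = (placed.insert_end - placed.insert_start) + placed.tsd_len - placed.deletion
            region2 = (
                parent.chrom,
                max(0, glo + shift - region_pad),
                min(len(donor[parent.chrom]), ghi + shift + region_pad),
            )
            pairs += simulate_reads(
                donor,
                read_params,
                n_pairs_for(region2[2] - region2[1], pd),
                rng,
                region=region2,
                name_prefix=f"{sample_id}.par",
            )
    truths = write_oracle_alignments(pairs, maps, ref_lengths, out_sam, min_anchor)
    return SampleSim(sample_id, placed, pairs, Path(out_sam), truths)
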