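"""Gene models, exon-exon junctions and reference artifacts.

This module reads the three reference inputs every retrocopy scan needs —
a gene annotation (GTF/GFF3), a catalog of already-known processed
pseudogenes (BED), and the reference genome (FASTA) — and builds the
in-memory junction model the evidence scanners query.

All coordinates are 0-based half-open internally.  Conversion to and from
1-based conventions (GTF, SAM display) happens only inside readers and
writers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pyfaidx
from intervaltree import IntervalTree

logger = logging.getLogger("retroscan")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonInterval:
    """One exon, 0-based half-open, with its 1-based rank in transcription order.

    On the '+' strand rank order equals genomic order; on the '-' strand
    rank 1 is the genomically last exon.
    """

    chrom: str
    start: int
    end: int
    rank: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"exon start must be < end: {self.start}..{self.end}")
        if self.rank < 1:
            raise ValueError("exon rank must be >= 1")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Junction:
    """An intron: ``donor`` is the first intronic base, ``acceptor`` one past
    the last intronic base, so the interval [donor, acceptor) is the intron."""

    chrom: str
    donor: int
    acceptor: int
    gene_id: str
    intron_rank: int

    def __post_init__(self) -> None:
        if not self.donor < self.acceptor:
            raise ValueError("junction donor must be < acceptor")


@dataclass
class Transcript:
    transcript_id: str
    exons: list[ExonInterval]  # genomic order

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    @property
    def exonic_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class GeneModel:
    """A gene with one or more transcripts of ordered exons.

    Junctions are derived, not stored: the junction set of a gene is the
    union over its transcripts, and intron ranks are reported from the
    canonical transcript (longest exonic span, ties broken by smallest
    transcript id) so that statements like "intron 18 of the host gene"
    are reproducible whatever the annotation's transcript order.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    transcripts: list[Transcript]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        for t in self.transcripts:
            for e in t.exons:
                if e.chrom != self.chrom:
                    raise ValueError(
                        f"exon chrom {e.chrom} differs from gene chrom {self.chrom}"
                    )

    @property
    def canonical_transcript(self) -> Transcript:
        return min(self.transcripts, key=lambda t: (-t.exonic_length, t.transcript_id))

    @property
    def locus(self) -> tuple[int, int]:
        """Genomic span covered by any transcript."""
        starts = [t.span[0] for t in self.transcripts]
        ends = [t.span[1] for t in self.transcripts]
        return min(starts), max(ends)

    @property
    def is_multi_exon(self) -> bool:
        return any(len(t.exons) >= 2 for t in self.transcripts)

    def junctions(self) -> list[Junction]:
        """Union of exon-exon junctions over transcripts, canonical ranks."""
        canonical = {}
        for donor, acceptor, rank in _transcript_junctions(
            self.canonical_transcript, self.strand
        ):
            canonical[(donor, acceptor)] = rank
        seen: dict[tuple[int, int], int] = dict(canonical)
        for t in self.transcripts:
            for donor, acceptor, rank in _transcript_junctions(t, self.strand):
                seen.setdefault((donor, acceptor), rank)
        return [
            Junction(self.chrom, d, a, self.gene_id, r)
            for (d, a), r in sorted(seen.items())
        ]


def _transcript_junctions(t: Transcript, strand: str):
    n = len(t.exons)
    for i in range(n - 1):
        donor = t.exons[i].end
        acceptor = t.exons[i + 1].start
        rank = i + 1 if strand == "+" else n - 1 - i
        yield donor, acceptor, rank


def make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    gene_name: str | None = None,
    transcript_id: str | None = None,
) -> GeneModel:
    """Convenience constructor for a single-transcript gene from (start, end)
    pairs in any order; ranks are assigned per the strand convention."""
    ordered = sorted(exons)
    n = len(ordered)
    ranked = [
        ExonInterval(chrom, s, e, rank=(i + 1 if strand == "+" else n - i))
        for i, (s, e) in enumerate(ordered)
    ]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_name or gene_id,
        chrom=chrom,
        strand=strand,
        transcripts=[Transcript(transcript_id or f"{gene_id}.t1", ranked)],
    )


# ---------------------------------------------------------------------------
# junction index
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureHit:
    """Result of a positional feature lookup: which gene, what feature
    (exonic/intronic) and the 1-based exon or intron rank when known."""

    gene_id: str
    gene_name: str
    feature: str  # 'exonic' | 'intronic'
    rank: int | None
    span: tuple[int, int]  # gene locus, used for smallest-containing-gene rules


class JunctionIndex:
    """Exact junction lookup plus positional feature lookup over a gene set."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._junctions: dict[tuple[str, int, int], list[tuple[str, int]]] = {}
        self._gene_tree: dict[str, IntervalTree] = {}
        self._exon_tree: dict[str, IntervalTree] = {}
        for gene in genes:
            if gene.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {gene.gene_id}")
            self.genes[gene.gene_id] = gene
            for j in gene.junctions():
                self._junctions.setdefault((j.chrom, j.donor, j.acceptor), []).append(
                    (gene.gene_id, j.intron_rank)
                )
            lo, hi = gene.locus
            self._gene_tree.setdefault(gene.chrom, IntervalTree()).addi(
                lo, hi, gene.gene_id
            )
            if gene.is_multi_exon:
                tree = self._exon_tree.setdefault(gene.chrom, IntervalTree())
                for t in gene.transcripts:
                    for e in t.exons:
                        tree.addi(e.start, e.end, gene.gene_id)
        if not self.genes:
            raise ValueError("cannot index an empty gene set")

    # -- junction queries ---------------------------------------------------

    def match_junction(
        self, chrom: str, donor: int, acceptor: int, slack: int = 0
    ) -> list[tuple[str, int]]:
        """Genes/intron-ranks whose junction matches within +/- slack on each
        boundary.  slack=0 is an exact lookup."""
        if slack == 0:
            return list(self._junctions.get((chrom, donor, acceptor), []))
        return sorted({(g, r) for g, r, _d, _a in
                       self.match_junction_full(chrom, donor, acceptor, slack)})

    def match_junction_full(
        self, chrom: str, donor: int, acceptor: int, slack: int = 0
    ) -> list[tuple[str, int, int, int]]:
        """Like match_junction but returns the *annotated* coordinates of
        each hit as (gene_id, intron_rank, donor, acceptor)."""
        hits: set[tuple[str, int, int, int]] = set()
        for dd in range(-slack, slack + 1):
            for da in range(-slack, slack + 1):
                key = (chrom, donor + dd, acceptor + da)
                for g, r in self._junctions.get(key, []):
                    hits.add((g, r, key[1], key[2]))
        return sorted(hits)

    def n_junctions(self, gene_id: str) -> int:
        return len(self.genes[gene_id].junctions())

    # -- positional queries -------------------------------------------------

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._gene_tree.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos))

    def feature_at(self, chrom: str, pos: int) -> list[FeatureHit]:
        """Feature classification of a position for every overlapping gene.

        Within a gene, a position is exonic if it falls in any transcript's
        exon (rank from the canonical transcript when it is a canonical
        exon), else intronic with the canonical intron rank.  Positions in
        no gene return an empty list (intergenic).
        """
        hits = []
        for gene_id in self.genes_at(chrom, pos):
            gene = self.genes[gene_id]
            hits.append(self._classify_in_gene(gene, pos))
        hits.sort(key=lambda h: (h.span[1] - h.span[0], h.gene_name))
        return hits

    @staticmethod
    def _classify_in_gene(gene: GeneModel, pos: int) -> FeatureHit:
        canon = gene.canonical_transcript
        for e in canon.exons:
            if e.start <= pos < e.end:
                return FeatureHit(
                    gene.gene_id, gene.gene_name, "exonic", e.rank, gene.locus
                )
        for t in gene.transcripts:
            for e in t.exons:
                if e.start <= pos < e.end:
                    return FeatureHit(
                        gene.gene_id, gene.gene_name, "exonic", e.rank, gene.locus
                    )
        # intronic: count canonical exons entirely left of pos
        n = len(canon.exons)
        left = sum(1 for e in canon.exons if e.end <= pos)
        if canon.span[0] <= pos < canon.span[1] and 1 <= left <= n - 1:
            rank = left if gene.strand == "+" else n - left
        else:  # inside the gene locus but outside the canonical transcript
            rank = None
        return FeatureHit(gene.gene_id, gene.gene_name, "intronic", rank, gene.locus)

    def exon_overlap_genes(self, chrom: str, start: int, end: int) -> list[str]:
        """Multi-exon genes with >= 1 exonic base overlapping [start, end)."""
        tree = self._exon_tree.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def locus(self, gene_id: str) -> tuple[str, int, int]:
        g = self.genes[gene_id]
        lo, hi = g.locus
        return g.chrom, lo, hi


def build_junction_index(genes: Iterable[GeneModel]) -> JunctionIndex:
    return JunctionIndex(genes)


# ---------------------------------------------------------------------------
# GTF / GFF3 reading and writing
# ---------------------------------------------------------------------------

DEFAULT_BIOTYPES = frozenset({"protein_coding"})


def _prevalidate_annotation(path: str | Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start > end:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: start > end ({start} > {end})"
                )


def _attr(feature, *names: str) -> str | None:
    for name in names:
        if name in feature.attributes:
            vals = feature.attributes[name]
            if vals:
                return vals[0]
    return None


def read_gene_annotation(
    path: str | Path,
    allowed_biotypes: frozenset[str] | set[str] | None = DEFAULT_BIOTYPES,
) -> list[GeneModel]:
    """Read gene/transcript/exon features from a GTF or GFF3 file.

    Exons are grouped per transcript, sorted genomically, and ranked in
    transcription order.  Genes whose biotype is outside
    ``allowed_biotypes`` are dropped (pass None to keep everything; genes
    without a biotype attribute are kept).
    """
    _prevalidate_annotation(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    # id -> (gene_id on GFF3 Parent chains)
    parent_of: dict[str, str] = {}
    gene_meta: dict[str, dict] = {}
    for ftype in ("gene", "transcript", "mRNA"):
        for f in db.features_of_type(ftype):
            fid = _attr(f, "ID") or _attr(f, "gene_id" if ftype == "gene" else "transcript_id")
            if ftype == "gene" and fid is not None:
                gene_meta[fid] = {
                    "gene_id": _attr(f, "gene_id") or fid,
                    "gene_name": _attr(f, "gene_name", "Name"),
                    "biotype": _attr(f, "gene_biotype", "gene_type", "biotype"),
                    "strand": f.strand,
                    "chrom": f.seqid,
                }
            elif fid is not None:
                parents = f.attributes.get("Parent", []) or f.attributes.get(
                    "gene_id", []
                )
                if parents:
                    parent_of[fid] = parents[0]

    # (gene_id, transcript_id) -> exon interval list
    exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    info: dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        tid = _attr(f, "transcript_id") or _attr(f, "Parent")
        if tid is None:
            logger.warning(
                "skipping exon at %s:%d-%d without a transcript attribute",
                f.seqid,
                f.start,
                f.end,
            )
            continue
        gid = _attr(f, "gene_id") or parent_of.get(tid)
        if gid is None:
            logger.warning("skipping exon of transcript %s with no gene", tid)
            continue
        meta = gene_meta.get(gid, {})
        rec = info.setdefault(
            gid,
            {
                "gene_name": _attr(f, "gene_name") or meta.get("gene_name") or gid,
                "chrom": f.seqid,
                "strand": f.strand if f.strand in "+-" else meta.get("strand", "+"),
                "biotype": _attr(f, "gene_biotype", "gene_type")
                or meta.get("biotype"),
            },
        )
        if rec["biotype"] is None:
            rec["biotype"] = _attr(f, "gene_biotype", "gene_type") or meta.get("biotype")
        exons.setdefault((gid, tid), []).append((f.start - 1, f.end))  # GTF is 1-based

    genes: list[GeneModel] = []
    by_gene: dict[str, list[str]] = {}
    for gid, tid in exons:
        by_gene.setdefault(gid, []).append(tid)
    for gid in sorted(by_gene):
        rec = info[gid]
        if (
            allowed_biotypes is not None
            and rec["biotype"] is not None
            and rec["biotype"] not in allowed_biotypes
        ):
            continue
        transcripts = []
        for tid in sorted(by_gene[gid]):
            ordered = sorted(exons[(gid, tid)])
            n = len(ordered)
            ranked = [
                ExonInterval(
                    rec["chrom"], s, e, rank=(i + 1 if rec["strand"] == "+" else n - i)
                )
                for i, (s, e) in enumerate(ordered)
            ]
            transcripts.append(Transcript(tid, ranked))
        genes.append(
            GeneModel(
                gene_id=gid,
                gene_name=rec["gene_name"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                transcripts=transcripts,
            )
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "retroscan") -> None:
    """Write gene/transcript/exon GTF lines (1-based inclusive on disk)."""
    with open(path, "w") as out:
        for gene in genes:
            lo, hi = gene.locus
            base = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'gene_biotype "protein_coding";'
            )
            out.write(
                f"{gene.chrom}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{gene.strand}\t.\t{base}\n"
            )
            for t in gene.transcripts:
                tlo, thi = t.span
                tattr = f'{base} transcript_id "{t.transcript_id}";'
                out.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{tlo + 1}\t{thi}\t.\t"
                    f"{gene.strand}\t.\t{tattr}\n"
                )
                for e in t.exons:
                    out.write(
                        f"{gene.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                        f'{gene.strand}\t.\t{tattr} exon_number "{e.rank}";\n'
                    )


# ---------------------------------------------------------------------------
# known processed-pseudogene catalog (BED)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KnownPsgRecord:
    chrom: str
    start: int
    end: int
    name: str
    parent_gene_name: str | None = None


@dataclass
class KnownPsgCatalog:
    records: list[KnownPsgRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def overlapping(self, chrom: str, start: int, end: int) -> list[KnownPsgRecord]:
        return [
            r
            for r in self.records
            if r.chrom == chrom and r.start < end and start < r.end
        ]


#: default rule for deriving a parent gene name from a pseudogene name:
#: strip a trailing "P<digits>" (e.g. CBX3P1 -> CBX3).
PARENT_NAME_PATTERN = re.compile(r"P\d+$")


def read_known_psg_bed(
    path: str | Path, parent_pattern: re.Pattern | str = PARENT_NAME_PATTERN
) -> KnownPsgCatalog:
    """Read a BED3+ catalog of known processed pseudogenes.

    The parent gene name is taken from column 5 when present, otherwise
    derived from the name column by stripping ``parent_pattern``.
    Records with start >= end are rejected with a warning.
    """
    if isinstance(parent_pattern, str):
        parent_pattern = re.compile(parent_pattern)
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s: line %d: fewer than 3 BED columns, skipped", path, lineno)
                continue
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                logger.warning(
                    "%s: line %d: invalid interval %d..%d rejected", path, lineno, start, end
                )
                continue
            name = fields[3] if len(fields) > 3 and fields[3] else f"{chrom}:{start}-{end}"
            if len(fields) > 4 and fields[4] and not fields[4].isdigit():
                parent = fields[4]
            else:
                stripped = parent_pattern.sub("", name)
                parent = stripped if stripped and stripped != name else None
            records.append(KnownPsgRecord(chrom, start, end, name, parent))
    return KnownPsgCatalog(records)


# ---------------------------------------------------------------------------
# genome access
# ---------------------------------------------------------------------------


class Genome:
    """Random-access FASTA reader returning uppercase sequence.

    Thin wrapper over pyfaidx with strict bounds checking; also usable
    from an in-memory dict of sequences (the simulator's donor genomes).
    """

    def __init__(self, source: str | Path | dict[str, str]):
        if isinstance(source, dict):
            self._seqs: dict[str, str] | None = {k: v.upper() for k, v in source.items()}
            self._fasta = None
            self._lengths = {k: len(v) for k, v in source.items()}
        else:
            self._seqs = None
            self._fasta = pyfaidx.Fasta(str(source), sequence_always_upper=True)
            self._lengths = {name: len(rec) for name, rec in self._fasta.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._lengths:
            raise KeyError(f"unknown sequence {chrom!r}")
        if start < 0 or end > self._lengths[chrom] or start > end:
            raise ValueError(
                f"fetch {chrom}:{start}-{end} out of range (length {self._lengths[chrom]})"
            )
        if start == end:
            return ""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end])


def read_genome(path: str | Path) -> Genome:
    return Genome(path)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")
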