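"""Calling retrocopy candidates and their insertion sites from evidence.

Spliced-read counts per gene nominate processed-pseudogene candidates;
chimeric-pair distal positions and chimeric-read breakpoints are clustered
by single linkage to localise each candidate's insertion site(s).  Sites
are tiered by their evidence (CP-CR / CP / CR), annotated with the host
feature (exonic / intronic / intergenic), and given an orientation call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import GeneModel, JunctionIndex, KnownPsgCatalog, KnownPsgRecord
from .evidence import EvidenceSet

logger = logging.getLogger("retroscan")


@dataclass
class CallParams:
    min_sr: int = 3  # minimum spliced reads to nominate a candidate
    min_junctions: int = 1  # minimum distinct junctions supported
    window: int = 500  # single-linkage clustering window, bp


@dataclass
class PsgCandidate:
    gene_id: str
    gene_name: str
    junctions_supported: list[tuple[int, int, int]]  # (donor, acceptor, SR count)
    total_sr: int
    distinct_junctions: int
    fraction_junctions_covered: float


@dataclass(frozen=True)
class ClusterMember:
    chrom: str
    pos: int
    kind: str  # 'CP' | 'CR'
    gene_strand: str  # strand of the gene-side alignment
    distal_strand: str
    clip_side: str | None = None  # CR only
    read_name: str = ""


@dataclass
class Cluster:
    gene_id: str
    members: list[ClusterMember]

    @property
    def chrom(self) -> str:
        return self.members[0].chrom

    @property
    def positions(self) -> list[int]:
        return [m.pos for m in self.members]


@dataclass
class InsertionSite:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    tier: str  # 'CP-CR' | 'CP' | 'CR'
    cp_count: int
    cr_count: int
    feature: str = "intergenic"
    host_gene: str | None = None
    host_rank: int | None = None
    orientation: str = "unknown"  # forward | reverse | unknown, vs host strand
    unanchored: bool = False  # True when no base-precise CR anchors the interval
    known: bool = False
    metadata: dict = field(default_factory=dict)


@dataclass
class SampleResult:
    sample_id: str
    candidates: list[PsgCandidate] = field(default_factory=list)
    sites: list[InsertionSite] = field(default_factory=list)
    known_matches: list[tuple[str, KnownPsgRecord]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# candidate nomination
# ---------------------------------------------------------------------------


def call_candidates(
    ev: EvidenceSet, index: JunctionIndex, params: CallParams | None = None
) -> list[PsgCandidate]:
    """One candidate per gene passing the spliced-read thresholds."""
    params = params or CallParams()
    if params.min_sr < 1 or params.min_junctions < 1:
        raise ValueError("min_sr and min_junctions must be >= 1")
    out = []
    for gene_id, records in sorted(ev.sr_by_gene().items()):
        counts: dict[tuple[int, int, int], int] = {}
        for rec in records:
            for j in rec.junctions_matched:
                counts[j] = counts.get(j, 0) + 1
        total_sr = len(records)
        distinct = len({(d, a) for d, a, _ in counts})
        if total_sr < params.min_sr or distinct < params.min_junctions:
            continue
        gene = index.genes[gene_id]
        n_junc = index.n_junctions(gene_id)
        out.append(
            PsgCandidate(
                gene_id=gene_id,
                gene_name=gene.gene_name,
                junctions_supported=sorted(
                    (d, a, c) for (d, a, _r), c in counts.items()
                ),
                total_sr=total_sr,
                distinct_junctions=distinct,
                fraction_junctions_covered=distinct / n_junc if n_junc else 0.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# insertion-site clustering
# ---------------------------------------------------------------------------


def cluster_insertion_evidence(
    ev: EvidenceSet,
    gene_id: str,
    index: JunctionIndex,
    window: int = 500,
) -> list[Cluster]:
    """Single-linkage clustering of CP distal positions and CR breakpoints.

    Positions inside the parent gene's own locus (padded by ``window``) are
    excluded — evidence pointing back at the parent localises nothing.
    Unanchored CR records never join clusters.  Positions are processed in
    sorted order, which makes single linkage in one dimension a simple
    chain rule and the result permutation-invariant.
    """
    chrom_p, lo, hi = index.locus(gene_id)
    members: list[ClusterMember] = []
    for cp in ev.pairs:
        if cp.gene_id != gene_id:
            continue
        chrom, pos, strand = cp.distal_mate
        if chrom == chrom_p and lo - window <= pos < hi + window:
            continue
        members.append(
            ClusterMember(
                chrom, pos, "CP", cp.gene_mate[2], strand, None, cp.read_name
            )
        )
    for cr in ev.clips:
        if cr.gene_id != gene_id or cr.unanchored:
            continue
        chrom, pos = cr.breakpoint
        if chrom == chrom_p and lo - window <= pos < hi + window:
            continue
        members.append(
            ClusterMember(
                chrom,
                pos,
                "CR",
                cr.gene_side[2],
                cr.distal_strand,
                cr.clip_side,
                cr.read_name,
            )
        )
    members.sort(key=lambda m: (m.chrom, m.pos, m.kind, m.read_name))
    clusters: list[Cluster] = []
    for m in members:
        if (
            clusters
            and clusters[-1].members[-1].chrom == m.chrom
            and m.pos - clusters[-1].members[-1].pos <= window
        ):
            clusters[-1].members.append(m)
        else:
            clusters.append(Cluster(gene_id, [m]))
    return clusters


def resolve_site(cluster: Cluster, index: JunctionIndex) -> InsertionSite:
    """Resolve a cluster into a called insertion site.

    With chimeric-read breakpoints present the site interval spans them
    base-precisely (min..max); a CP-only cluster yields an approximate
    single-base interval at the median distal position, with the full
    cluster span kept as metadata.
    """
    if not cluster.members:
        raise ValueError("cannot resolve an empty cluster")
    cr = [m for m in cluster.members if m.kind == "CR"]
    cp = [m for m in cluster.members if m.kind == "CP"]
    gene = index.genes[cluster.gene_id]
    meta: dict = {}
    if cr:
        start = min(m.pos for m in cr)
        end = max(m.pos for m in cr) + 1
        unanchored = False
        right_bps = [m.pos for m in cr if m.clip_side == "right"]
        left_bps = [m.pos for m in cr if m.clip_side == "left"]
        if right_bps and left_bps:
            offset = max(right_bps) - min(left_bps)
            if offset >= 0:
                meta["tsd_len"] = offset
            else:
                meta["deletion_len"] = -offset
    else:
        positions = sorted(m.pos for m in cp)
        median = positions[(len(positions) - 1) // 2]
        start, end = median, median + 1
        unanchored = True
        meta["cluster_span"] = (positions[0], positions[-1] + 1)
    tier = "CP-CR" if (cp and cr) else ("CR" if cr else "CP")
    site = InsertionSite(
        gene_id=cluster.gene_id,
        gene_name=gene.gene_name,
        chrom=cluster.chrom,
        start=start,
        end=end,
        tier=tier,
        cp_count=len(cp),
        cr_count=len(cr),
        unanchored=unanchored,
        metadata=meta,
    )
    return annotate_site(site, index)


def annotate_site(site: InsertionSite, index: JunctionIndex) -> InsertionSite:
    """Host feature at the site midpoint.

    If several genes contain the midpoint the smallest gene span wins
    (ties alphabetically by gene name, logged).
    """
    mid = (site.start + site.end) // 2
    hits = index.feature_at(site.chrom, mid)
    if not hits:
        site.feature = "intergenic"
        site.host_gene = None
        site.host_rank = None
        site.metadata["host_strand"] = "+"
        return site
    if len(hits) > 1 and (hits[0].span[1] - hits[0].span[0]) == (
        hits[1].span[1] - hits[1].span[0]
    ):
        logger.debug(
            "site %s:%d midpoint in %d equally-sized genes; choosing %s",
            site.chrom,
            site.start,
            len(hits),
            hits[0].gene_name,
        )
    best = hits[0]
    site.feature = best.feature
    site.host_gene = best.gene_name
    site.host_rank = best.rank
    site.metadata["host_strand"] = index.genes[best.gene_id].strand
    return site


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


def infer_orientation(
    cluster: Cluster, parent: GeneModel, host_strand: str = "+"
) -> str:
    """Majority-vote reading orientation of the retrocopy vs the host strand.

    Each evidence record implies the strand of the inserted copy on the
    reference: for a chimeric read, gene-side and distal-side pieces come
    from the same sequenced read, so equal strands mean the copy runs in
    the parent's direction; for a chimeric pair the mates are sequenced in
    opposite directions, so the expectation flips.  The implied reference
    strand of the copy is then compared with the host gene's strand
    ('+' when intergenic).
    """
    votes: list[str] = []
    for m in cluster.members:
        same = m.gene_strand == m.distal_strand
        if m.kind == "CR":
            copy_dir = "+" if same else "-"  # direction of mRNA along reference
        else:  # CP: FR mate geometry flips the expectation
            copy_dir = "-" if same else "+"
        # copy_dir '+' means the copy reads in the parent-aligned direction;
        # compose with the parent strand to get the reference strand of the copy
        ref_strand = parent.strand if copy_dir == "+" else ("-" if parent.strand == "+" else "+")
        votes.append("forward" if ref_strand == host_strand else "reverse")
    if not votes:
        return "unknown"
    fwd = votes.count("forward")
    rev = votes.count("reverse")
    if fwd == rev:
        return "unknown"
    return "forward" if fwd > rev else "reverse"


# ---------------------------------------------------------------------------
# known-catalog matching
# ---------------------------------------------------------------------------


def match_known(
    candidates: list[PsgCandidate],
    sites: list[InsertionSite],
    catalog: KnownPsgCatalog,
) -> list[tuple[str, KnownPsgRecord]]:
    """Label sites overlapping the known-pseudogene catalog.

    A site matches a record when their intervals overlap by >= 1 bp and,
    if the catalog names a parent gene, that name equals the candidate's
    gene name.  Matched sites are flagged ``known``; the return value
    pairs each matched gene name with the catalog record.
    """
    by_gene = {c.gene_id: c for c in candidates}
    matches: list[tuple[str, KnownPsgRecord]] = []
    for site in sites:
        cand = by_gene.get(site.gene_id)
        for rec in catalog.overlapping(site.chrom, site.start, site.end):
            if rec.parent_gene_name is not None and (
                cand is None or rec.parent_gene_name != cand.gene_name
            ):
                continue
            site.known = True
            matches.append((site.gene_name, rec))
    return matches


# ---------------------------------------------------------------------------
# per-sample orchestration
# ---------------------------------------------------------------------------


def call_sample(
    ev: EvidenceSet,
    index: JunctionIndex,
    sample_id: str = "sample",
    params: CallParams | None = None,
    catalog: KnownPsgCatalog | None = None,
) -> SampleResult:
    """Evidence -> candidates -> clustered, annotated, oriented sites."""
    params = params or CallParams()
    candidates = call_candidates(ev, index, params)
    sites: list[InsertionSite] = []
    for cand in candidates:
        for cluster in cluster_insertion_evidence(
            ev, cand.gene_id, index, params.window
        ):
            site = resolve_site(cluster, index)
            site.orientation = infer_orientation(
                cluster,
                index.genes[cand.gene_id],
                site.metadata.get("host_strand", "+"),
            )
            sites.append(site)
    sites.sort(key=lambda s: (s.gene_id, s.chrom, s.start))
    result = SampleResult(sample_id=sample_id, candidates=candidates, sites=sites)
    if catalog is not None:
        result.known_matches = match_known(candidates, sites, catalog)
    return result
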