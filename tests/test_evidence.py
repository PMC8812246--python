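"""Classification of spliced reads, chimeric pairs and chimeric reads."""

import pytest

from retroscan import (
    ScanParams,
    build_junction_index,
    classify_chimeric_pair,
    extract_chimeric_read,
    make_gene,
    match_spliced_read,
    scan_alignments,
)
from retroscan.evidence import AlignedReadView, SupplementaryTarget, parse_cigar


def make_view(chrom="chr1", pos=0, cigar="90M", mapq=60, strand="+",
              mate=None, supp=(), name="r1", read1=True):
    mate_chrom, mate_pos, mate_strand = mate if mate else (None, None, None)
    return AlignedReadView(
        read_name=name,
        chrom=chrom,
        pos=pos,
        cigar=parse_cigar(cigar),
        mapq=mapq,
        strand=strand,
        is_paired=mate is not None,
        is_read1=read1,
        is_primary=True,
        mate_chrom=mate_chrom,
        mate_pos=mate_pos,
        mate_strand=mate_strand,
        supplementary_targets=[
            SupplementaryTarget(c, p, s, tuple(parse_cigar(cg))) for c, p, s, cg in supp
        ],
    )


class TestSplicedRead:
    def test_exact_junction_match(self, toy_index):
        view = make_view(pos=155, cigar="45M100N45M")
        ev = match_spliced_read(view, toy_index, slack=0)
        assert ev is not None
        assert ev.junctions_matched == ((200, 300, 1),)

    def test_slack_boundary(self, toy_index):
        view = make_view(pos=156, cigar="45M99N45M")  # N spans 201..300
        assert match_spliced_read(view, toy_index, slack=0) is None
        ev = match_spliced_read(view, toy_index, slack=1)
        assert ev is not None and ev.junctions_matched == ((200, 300, 1),)

    def test_two_gap_read_matches_both_introns(self):
        gene = make_gene("g", "chr1", "+", [(100, 200), (300, 330), (530, 560)])
        index = build_junction_index([gene])
        view = make_view(pos=170, cigar="30M100N30M200N30M")
        ev = match_spliced_read(view, index)
        assert ev is not None
        assert ev.junctions_matched == ((200, 300, 1), (330, 530, 2))

    def test_ambiguous_gene_assignment_drops_read(self):
        g1 = make_gene("a", "chr1", "+", [(100, 200), (300, 400)])
        g2 = make_gene("b", "chr1", "-", [(150, 200), (300, 350)])
        index = build_junction_index([g1, g2])
        view = make_view(pos=155, cigar="45M100N45M")  # matches both genes' junction
        assert match_spliced_read(view, index) is None

    def test_unspliced_read_matches_nothing(self, toy_index):
        assert match_spliced_read(make_view(pos=100, cigar="90M"), toy_index) is None


class TestChimericPair:
    def test_mate_on_other_chromosome(self, toy_index):
        view = make_view(pos=120, mate=("chr9", 5000, "-"))
        ev = classify_chimeric_pair(view, toy_index)
        assert ev is not None and ev.distal_mate == ("chr9", 5000, "-")

    def test_concordant_pair_within_locus(self, toy_index):
        view = make_view(pos=110, mate=("chr1", 350, "-"))
        assert classify_chimeric_pair(view, toy_index, 10_000) is None

    def test_distant_mate_same_chromosome(self, toy_index):
        view = make_view(pos=110, mate=("chr1", 50_000, "-"))
        assert classify_chimeric_pair(view, toy_index, 10_000) is not None

    def test_non_exonic_read_yields_nothing(self, toy_index):
        view = make_view(pos=210, cigar="50M", mate=("chr9", 5000, "-"))
        assert classify_chimeric_pair(view, toy_index) is None


@pytest.fixture(scope="module")
def host_and_parent_index():
    # large 21-exon host gene on chr9 and a compact parent gene on chr18
    host = make_gene(
        "host", "chr9", "+", [(1000 * i, 1000 * i + 200) for i in range(1, 22)]
    )
    parent = make_gene("par", "chr18", "-", [(500, 700), (900, 1100)])
    return build_junction_index([host, parent])


class TestChimericRead:

    def test_primary_at_host_supplementary_in_parent_exon(self, host_and_parent_index):
        # 60M30S in intron 18 of the host; the clipped tail maps to the parent
        view = make_view(
            chrom="chr9", pos=18_300, cigar="60M30S",
            supp=[("chr18", 1000, "-", "60S30M")],
        )
        ev = extract_chimeric_read(view, host_and_parent_index, min_clip=20)
        assert ev is not None and not ev.unanchored
        assert ev.gene_id == "par"
        assert ev.breakpoint == ("chr9", 18_360)  # one past the aligned portion
        assert ev.clip_side == "right"

    def test_primary_in_parent_supplementary_at_host(self, host_and_parent_index):
        view = make_view(
            chrom="chr18", pos=1040, cigar="60M30S",
            supp=[("chr9", 18_300, "+", "60S30M")],
        )
        ev = extract_chimeric_read(view, host_and_parent_index, min_clip=20)
        assert ev is not None and not ev.unanchored
        assert ev.gene_id == "par"
        # host-side alignment is left-clipped: breakpoint at its leftmost base
        assert ev.breakpoint == ("chr9", 18_300)

    def test_unclipped_read_yields_nothing(self, host_and_parent_index):
        assert extract_chimeric_read(make_view(cigar="90M"), host_and_parent_index) is None

    def test_short_clip_below_threshold(self, host_and_parent_index):
        view = make_view(chrom="chr18", pos=1000, cigar="10S80M")
        assert extract_chimeric_read(view, host_and_parent_index, min_clip=20) is None

    def test_clip_without_supplementary_is_unanchored(self, host_and_parent_index):
        view = make_view(chrom="chr18", pos=1040, cigar="60M30S")
        ev = extract_chimeric_read(view, host_and_parent_index, min_clip=20)
        assert ev is not None and ev.unanchored
        assert ev.breakpoint[0] == "chr18"


class TestScan:
    def test_empty_alignment_file(self, toy_index, tmp_path):
        import pysam

        path = tmp_path / "empty.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]}
        with pysam.AlignmentFile(path, "wh", header=header):
            pass
        ev = scan_alignments(path, toy_index)
        assert not ev.spliced and not ev.pairs and not ev.clips

    def test_simulated_sample_produces_all_streams(self, sim_sample, small_index):
        ev = scan_alignments(sim_sample.sam_path, small_index)
        assert ev.spliced and ev.pairs and ev.clips
        # every junction covered by a simulated spliced read is counted
        truth_junctions = {
            j for t in sim_sample.read_truths for j in t.junctions
        }
        for j in truth_junctions:
            assert ev.junction_sr_counts.get(j, 0) >= 1

    def test_no_read_contributes_twice_per_stream(self, sim_sample, small_index):
        ev = scan_alignments(sim_sample.sam_path, small_index)
        names = [e.read_name for e in ev.pairs]
        assert len(names) == len(set(names))
        for stream in (ev.spliced, ev.clips):
            # a name may appear for each mate, never more
            from collections import Counter

            assert max(Counter(e.read_name for e in stream).values()) <= 2

    def test_raising_min_mapq_never_increases_counts(self, sim_sample, small_index):
        lo = scan_alignments(sim_sample.sam_path, small_index, ScanParams(min_mapq=0))
        hi = scan_alignments(sim_sample.sam_path, small_index, ScanParams(min_mapq=61))
        assert len(hi.spliced) <= len(lo.spliced)
        assert len(hi.pairs) <= len(lo.pairs)
        assert len(hi.clips) <= len(lo.clips)
        assert not hi.spliced  # oracle alignments are mapq 60

    def test_negative_control_is_evidence_free(self, small_genome, small_index, tmp_path):
        from retroscan import ReadSimParams
        from retroscan.sim import simulate_sample

        ref, genes = small_genome
        sam = tmp_path / "neg.sam"
        simulate_sample(ref, genes, None, ReadSimParams(), depth=50, seed=5,
                        out_sam=sam, sample_id="neg")
        ev = scan_alignments(sam, small_index)
        assert not ev.spliced and not ev.pairs and not ev.clips
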