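"""Candidate calling, insertion-site clustering, annotation and orientation."""

import random

import pytest

from retroscan import (
    CallParams,
    build_junction_index,
    call_candidates,
    cluster_insertion_evidence,
    infer_orientation,
    make_gene,
    match_known,
    read_known_psg_bed,
    resolve_site,
)
from retroscan.calling import Cluster, ClusterMember, annotate_site, InsertionSite
from retroscan.evidence import (
    ChimericPairEvidence,
    ChimericReadEvidence,
    EvidenceSet,
    SplicedReadEvidence,
)


def make_parent_index(n_exons=5, chrom="chrP", extra_genes=()):
    exons = [(1000 * i, 1000 * i + 200) for i in range(1, n_exons + 1)]
    parent = make_gene("G1", chrom, "+", exons)
    return build_junction_index([parent, *extra_genes])


def sr(gene="G1", junctions=((1200, 2000, 1),), name="r"):
    return SplicedReadEvidence(name, gene, tuple(junctions), 60)


def cp(distal, gene="G1", gene_strand="+", name="p"):
    return ChimericPairEvidence(name, gene, ("chrP", 1100, gene_strand), distal, 60)


def cr(breakpoint, clip_side="left", gene="G1", gene_strand="+", distal_strand="+", name="c"):
    return ChimericReadEvidence(
        name, gene, breakpoint, clip_side, 30, ("chrP", 1100, gene_strand), distal_strand
    )


class TestCallCandidates:
    def test_threshold_boundary(self):
        index = make_parent_index(n_exons=5)
        ev = EvidenceSet(spliced=[sr(name=f"r{i}") for i in range(3)])
        [cand] = call_candidates(ev, index, CallParams(min_sr=3, min_junctions=1))
        assert cand.total_sr == 3 and cand.distinct_junctions == 1
        assert cand.fraction_junctions_covered == pytest.approx(1 / 4)

    def test_below_min_sr_is_silent(self):
        index = make_parent_index()
        ev = EvidenceSet(spliced=[sr(name=f"r{i}") for i in range(2)])
        assert call_candidates(ev, index, CallParams(min_sr=3)) == []

    def test_simulated_retrocopy_supports_every_junction(self, sim_result, small_index):
        [cand] = [c for c in sim_result.candidates if c.gene_id == "G002"]
        assert cand.distinct_junctions == small_index.n_junctions("G002")
        assert cand.fraction_junctions_covered == 1.0


class TestClustering:
    def test_mixed_evidence_groups_into_one_cluster(self):
        index = make_parent_index()
        ev = EvidenceSet(
            pairs=[cp(("chr9", p, "-"), name=f"p{p}") for p in (1000, 1200, 1350)],
            clips=[cr(("chr9", 1500), name="c1")],
        )
        [cluster] = cluster_insertion_evidence(ev, "G1", index, window=500)
        assert len(cluster.members) == 4

    def test_different_chromosomes_never_merge(self):
        index = make_parent_index()
        ev = EvidenceSet(
            pairs=[cp(("chr9", 1000, "-"), name="a"), cp(("chr8", 1000, "-"), name="b")]
        )
        assert len(cluster_insertion_evidence(ev, "G1", index, 500)) == 2

    def test_no_evidence_gives_no_clusters(self):
        index = make_parent_index()
        assert cluster_insertion_evidence(EvidenceSet(), "G1", index, 500) == []

    def test_parent_locus_positions_are_excluded(self):
        index = make_parent_index()
        ev = EvidenceSet(pairs=[cp(("chrP", 3000, "-"), name="inlocus")])
        assert cluster_insertion_evidence(ev, "G1", index, 500) == []

    def test_matches_brute_force_single_linkage(self):
        index = make_parent_index()
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(1, 50)
            positions = [rng.randint(0, 5000) for _ in range(n)]
            window = rng.randint(1, 800)
            ev = EvidenceSet(
                pairs=[cp(("chr9", p, "-"), name=f"p{i}") for i, p in enumerate(positions)]
            )
            got = sorted(
                sorted(c.positions)
                for c in cluster_insertion_evidence(ev, "G1", index, window)
            )
            assert got == brute_force_single_linkage(positions, window)

    def test_smaller_window_never_produces_larger_clusters(self):
        index = make_parent_index()
        positions = [100, 300, 700, 900, 2000]
        ev = EvidenceSet(
            pairs=[cp(("chr9", p, "-"), name=f"p{i}") for i, p in enumerate(positions)]
        )
        sizes = {}
        for window in (100, 300, 1200):
            clusters = cluster_insertion_evidence(ev, "G1", index, window)
            sizes[window] = sorted(len(c.members) for c in clusters)
        assert len(sizes[100]) >= len(sizes[300]) >= len(sizes[1200])


def brute_force_single_linkage(positions, window):
    """Union-find over all pairs within the window (quadratic oracle)."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(positions):
        groups.setdefault(find(i), []).append(p)
    return sorted(sorted(g) for g in groups.values())


class TestResolveSite:
    def test_two_breakpoints_span_base_precisely(self):
        # two chimeric-read breakpoints two bases apart plus pair support:
        # the called interval displays as a 3 bp site
        index = make_parent_index()
        members = [
            ClusterMember("chr9", 127_732_712, "CR", "+", "+", "right", "c1"),
            ClusterMember("chr9", 127_732_714, "CR", "+", "+", "left", "c2"),
            ClusterMember("chr9", 127_732_600, "CP", "+", "-", None, "p1"),
        ]
        site = resolve_site(Cluster("G1", members), index)
        assert (site.start, site.end) == (127_732_712, 127_732_715)
        assert f"{site.chrom}:{site.start + 1}-{site.end}" == "chr9:127732713-127732715"
        assert site.tier == "CP-CR"

    def test_single_breakpoint_is_single_base(self):
        index = make_parent_index()
        members = [
            ClusterMember("chr15", 40_854_179, "CR", "+", "+", "left", "c"),
            ClusterMember("chr15", 40_854_000, "CP", "+", "-", None, "p"),
        ]
        site = resolve_site(Cluster("G1", members), index)
        assert f"{site.chrom}:{site.start + 1}-{site.end}" == "chr15:40854180-40854180"

    def test_cp_only_cluster_uses_median(self):
        index = make_parent_index()
        members = [
            ClusterMember("chr9", p, "CP", "+", "-", None, f"p{p}")
            for p in (5000, 5400, 5600)
        ]
        site = resolve_site(Cluster("G1", members), index)
        assert (site.start, site.end) == (5400, 5401)
        assert site.tier == "CP" and site.unanchored
        assert site.metadata["cluster_span"] == (5000, 5601)

    def test_tsd_metadata_from_opposing_clips(self):
        index = make_parent_index()
        members = [
            ClusterMember("chr9", 5004, "CR", "+", "+", "right", "a"),
            ClusterMember("chr9", 5000, "CR", "+", "+", "left", "b"),
        ]
        site = resolve_site(Cluster("G1", members), index)
        assert site.metadata["tsd_len"] == 4 and site.tier == "CR"


class TestAnnotateSite:
    def test_intron_18_of_large_host(self):
        host = make_gene(
            "host", "chr9", "+", [(10_000 * i, 10_000 * i + 200) for i in range(1, 22)]
        )
        index = build_junction_index([make_gene("G1", "chrP", "+", [(100, 200), (300, 400)]), host])
        site = InsertionSite("G1", "G1", "chr9", 185_000, 185_003, "CP-CR", 2, 2)
        annotate_site(site, index)
        assert site.feature == "intronic" and site.host_gene == "host"
        assert site.host_rank == 18

    def test_intergenic_site(self):
        index = make_parent_index()
        site = InsertionSite("G1", "G1", "chr9", 100, 101, "CP", 1, 0)
        annotate_site(site, index)
        assert site.feature == "intergenic" and site.host_gene is None

    def test_smallest_containing_gene_wins(self):
        big = make_gene("big", "chr2", "+", [(1000, 1200), (9000, 9200)])
        small = make_gene("small", "chr2", "-", [(4000, 4300), (5000, 5200)])
        index = build_junction_index(
            [make_gene("G1", "chrP", "+", [(100, 200), (300, 400)]), big, small]
        )
        site = InsertionSite("G1", "G1", "chr2", 4100, 4101, "CR", 0, 1)
        annotate_site(site, index)
        assert site.host_gene == "small" and site.feature == "exonic"


class TestOrientation:
    def test_single_chimeric_read_same_strands_is_forward(self):
        parent = make_gene("G1", "chrP", "+", [(100, 200), (300, 400)])
        cluster = Cluster("G1", [ClusterMember("chr9", 5000, "CR", "+", "+", "left", "c")])
        assert infer_orientation(cluster, parent, "+") == "forward"

    def test_relative_flip_on_plus_parent_is_reverse(self):
        parent = make_gene("G1", "chrP", "+", [(100, 200), (300, 400)])
        cluster = Cluster("G1", [ClusterMember("chr9", 5000, "CR", "+", "-", "left", "c")])
        assert infer_orientation(cluster, parent, "+") == "reverse"

    def test_tie_is_unknown(self):
        parent = make_gene("G1", "chrP", "+", [(100, 200), (300, 400)])
        cluster = Cluster(
            "G1",
            [
                ClusterMember("chr9", 5000, "CR", "+", "+", "left", "a"),
                ClusterMember("chr9", 5001, "CR", "+", "-", "left", "b"),
            ],
        )
        assert infer_orientation(cluster, parent, "+") == "unknown"

    def test_pair_evidence_flips_expectation(self):
        # opposite mate strands are the concordant geometry: forward copy
        parent = make_gene("G1", "chrP", "+", [(100, 200), (300, 400)])
        cluster = Cluster("G1", [ClusterMember("chr9", 5000, "CP", "+", "-", None, "p")])
        assert infer_orientation(cluster, parent, "+") == "forward"

    def test_simulated_reverse_insertion_recovered(self, sim_result):
        [site] = [s for s in sim_result.sites if s.gene_id == "G002"]
        assert site.orientation == "reverse"


class TestMatchKnown:
    @pytest.fixture
    def catalog(self, tmp_path):
        p = tmp_path / "known.bed"
        p.write_text("chr9\t5000\t5100\tCBX3P1\n")
        return read_known_psg_bed(p)

    def _candidate(self, gene_name="CBX3"):
        from retroscan.calling import PsgCandidate

        return PsgCandidate("G1", gene_name, [(200, 300, 5)], 5, 1, 1.0)

    def test_overlap_and_name_match(self, catalog):
        site = InsertionSite("G1", "CBX3", "chr9", 5050, 5051, "CR", 0, 1)
        matches = match_known([self._candidate()], [site], catalog)
        assert site.known and matches[0][1].name == "CBX3P1"

    def test_half_open_boundary_misses(self, catalog):
        site = InsertionSite("G1", "CBX3", "chr9", 4999, 5000, "CR", 0, 1)
        assert match_known([self._candidate()], [site], catalog) == []

    def test_name_mismatch_blocks_match(self, catalog):
        site = InsertionSite("G1", "SMAD4", "chr9", 5050, 5051, "CR", 0, 1)
        assert match_known([self._candidate("SMAD4")], [site], catalog) == []

    def test_empty_catalog_leaves_sites_novel(self):
        from retroscan.annotation import KnownPsgCatalog

        site = InsertionSite("G1", "CBX3", "chr9", 5050, 5051, "CR", 0, 1)
        assert match_known([self._candidate()], [site], KnownPsgCatalog()) == []
        assert not site.known
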