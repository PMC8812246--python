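"""Simulator: genome generation, retrocopy construction/insertion,
read simulation and the oracle alignment writer."""

import numpy as np
import pytest

from retroscan import (
    Genome,
    ReadSimParams,
    RetrocopySpec,
    build_retrocopy,
    generate_genome,
    insert_retrocopy,
    make_gene,
    reverse_complement,
    simulate_reads,
)
from retroscan.sim import ReadPair, oracle_alignments, simulate_sample


class TestGenerateGenome:
    def test_deterministic_per_seed(self, tmp_path):
        a_fa, a_gtf = tmp_path / "a.fa", tmp_path / "a.gtf"
        b_fa, b_gtf = tmp_path / "b.fa", tmp_path / "b.gtf"
        generate_genome(seed=5, out_fasta=a_fa, out_gtf=a_gtf)
        generate_genome(seed=5, out_fasta=b_fa, out_gtf=b_gtf)
        assert a_fa.read_bytes() == b_fa.read_bytes()
        assert a_gtf.read_bytes() == b_gtf.read_bytes()

    def test_single_gene_five_exons(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        _ref, genes = generate_genome(
            n_chroms=1, n_genes=1, exons_per_gene_range=(5, 5), seed=1, out_gtf=gtf
        )
        [gene] = genes
        assert len(gene.canonical_transcript.exons) == 5
        assert len(gene.junctions()) == 4
        assert sum(1 for l in gtf.read_text().splitlines() if "\texon\t" in l) == 5

    def test_two_exon_range_gives_one_junction_each(self):
        _ref, genes = generate_genome(n_genes=10, exons_per_gene_range=(2, 2), seed=2)
        assert all(len(g.junctions()) == 1 for g in genes)

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="cannot place gene"):
            generate_genome(n_chroms=1, chrom_len=8_000, n_genes=10, seed=3)


class TestBuildRetrocopy:
    @pytest.fixture
    def toy_ref(self):
        rng = np.random.default_rng(4)
        from retroscan.sim import _random_seq

        return {"chr1": _random_seq(rng, 2000)}

    def test_length_arithmetic(self, toy_ref):
        gene = make_gene("g", "chr1", "+", [(100, 200), (400, 500)])
        spec = RetrocopySpec("g", "chr1", 1500, polyA_len=10, tsd_len=0)
        seq = build_retrocopy(gene, Genome(toy_ref), spec)
        assert len(seq) == 210 and seq.endswith("A" * 10)

    def test_truncation(self, toy_ref):
        gene = make_gene("g", "chr1", "+", [(100, 200), (400, 500)])
        spec = RetrocopySpec("g", "chr1", 1500, polyA_len=10, five_prime_truncation=50)
        assert len(build_retrocopy(gene, Genome(toy_ref), spec)) == 160

    def test_minus_strand_equals_revcomp_oracle(self, toy_ref):
        gene = make_gene("g", "chr1", "-", [(100, 200), (400, 500)])
        spec = RetrocopySpec("g", "chr1", 1500, polyA_len=0, tsd_len=0)
        got = build_retrocopy(gene, Genome(toy_ref), spec)
        expected = reverse_complement(toy_ref["chr1"][100:200] + toy_ref["chr1"][400:500])
        assert got == expected

    def test_truncation_beyond_mrna_raises(self, toy_ref):
        gene = make_gene("g", "chr1", "+", [(100, 200)])
        spec = RetrocopySpec("g", "chr1", 1500, five_prime_truncation=150)
        with pytest.raises(ValueError, match="truncation"):
            build_retrocopy(gene, Genome(toy_ref), spec)


class TestInsertRetrocopy:
    def _setup(self, tsd=4, deletion=0, orientation="forward", spacer=""):
        rng = np.random.default_rng(8)
        from retroscan.sim import _random_seq

        ref = {"chr1": _random_seq(rng, 2000), "chr2": _random_seq(rng, 3000)}
        gene = make_gene("g", "chr1", "+", [(100, 200), (400, 500)])
        spec = RetrocopySpec(
            "g", "chr2", 1000, orientation=orientation, polyA_len=10,
            tsd_len=tsd, breakpoint_deletion=deletion, spacer=spacer,
        )
        retro = build_retrocopy(gene, Genome(ref), spec)
        donor, maps, placed = insert_retrocopy(ref, retro, spec, gene)
        return ref, retro, donor, placed

    def test_tsd_duplicates_host_bases(self):
        ref, retro, donor, placed = self._setup(tsd=4)
        dup = ref["chr2"][1000:1004]
        # the duplicated bases flank the insert on both sides
        assert donor["chr2"][1000:1004] == dup
        ins_end = 1004 + len(retro)
        assert donor["chr2"][ins_end : ins_end + 4] == dup
        assert placed.bp_left == 1004 and placed.bp_right == 1000

    @pytest.mark.parametrize(
        "tsd,deletion,spacer", [(0, 0, ""), (4, 0, ""), (11, 0, "ATTTTTTTTTTTAAAGA"), (0, 3, "")]
    )
    def test_length_conservation(self, tsd, deletion, spacer):
        ref, retro, donor, placed = self._setup(tsd=tsd, deletion=deletion, spacer=spacer)
        assert len(donor["chr2"]) == len(ref["chr2"]) + len(retro) + tsd - deletion + len(spacer)

    def test_reverse_orientation_inserts_revcomp(self):
        ref, retro, donor, placed = self._setup(tsd=0, orientation="reverse")
        ins = donor["chr2"][1000 : 1000 + len(retro)]
        assert ins == reverse_complement(retro)

    def test_out_of_range_position_raises(self):
        rng = np.random.default_rng(8)
        from retroscan.sim import _random_seq

        ref = {"chr1": _random_seq(rng, 2000)}
        gene = make_gene("g", "chr1", "+", [(100, 200), (400, 500)])
        spec = RetrocopySpec("g", "chr1", 1999, tsd_len=4)
        with pytest.raises(ValueError, match="out of range"):
            insert_retrocopy(ref, build_retrocopy(gene, Genome(ref), spec), spec, gene)

    def test_tsd_and_deletion_mutually_exclusive(self):
        with pytest.raises(ValueError):
            RetrocopySpec("g", "chr1", 10, tsd_len=2, breakpoint_deletion=2)


class TestSimulateReads:
    @pytest.fixture
    def donor(self):
        rng = np.random.default_rng(6)
        from retroscan.sim import _random_seq

        return {"chrD": _random_seq(rng, 5000)}

    def test_error_free_reads_are_substrings(self, donor):
        rng = np.random.default_rng(0)
        params = ReadSimParams(error_rate=0.0)
        for p in simulate_reads(donor, params, 50, rng):
            assert donor["chrD"][p.frag_start : p.frag_start + 90] == p.seq1
            assert reverse_complement(donor["chrD"][p.frag_end - 90 : p.frag_end]) == p.seq2

    def test_read_counts_and_lengths(self, donor):
        rng = np.random.default_rng(0)
        pairs = simulate_reads(donor, ReadSimParams(), 1000, rng)
        assert len(pairs) == 1000
        assert all(len(p.seq1) == 90 and len(p.seq2) == 90 for p in pairs)

    def test_error_rate_within_binomial_bounds(self, donor):
        rng = np.random.default_rng(1)
        pairs = simulate_reads(donor, ReadSimParams(error_rate=0.02), 500, rng)
        mismatches = sum(
            sum(a != b for a, b in zip(donor["chrD"][p.frag_start : p.frag_start + 90], p.seq1))
            for p in pairs
        )
        n = 500 * 90
        # substituting to a random different base always mismatches
        expected, sd = n * 0.02, (n * 0.02 * 0.98) ** 0.5
        assert abs(mismatches - expected) <= 3 * sd


class TestOracleAlignments:
    def _donor_with_insert(self, orientation="forward", tsd=4):
        rng = np.random.default_rng(9)
        from retroscan.sim import _random_seq

        ref = {"chrG": _random_seq(rng, 3000), "chrH": _random_seq(rng, 3000)}
        # two 100 bp exons separated by a 200 bp intron
        gene = make_gene("g", "chrG", "+", [(1000, 1100), (1300, 1400)])
        spec = RetrocopySpec(
            "g", "chrH", 1500, orientation=orientation, polyA_len=20, tsd_len=tsd
        )
        retro = build_retrocopy(gene, Genome(ref), spec)
        donor, maps, placed = insert_retrocopy(ref, retro, spec, gene)
        return ref, donor, maps, placed

    def test_junction_spanning_read_gets_n_gap_cigar(self):
        ref, donor, maps, placed = self._donor_with_insert()
        # read covering the last 40 bp of exon 1 and first 50 bp of exon 2
        s = placed.insert_start + 60
        pair = ReadPair("r", "chrH", s, s + 500, donor["chrH"][s : s + 90], "A" * 90)
        records, truths = oracle_alignments([pair], maps)
        primary = records[0]
        assert primary.chrom == "chrG"
        assert primary.pos == 1060
        assert primary.cigar == "40M200N50M"
        assert truths[0].junctions == [("chrG", 1100, 1300)]

    def test_breakpoint_read_is_split_with_sa(self):
        ref, donor, maps, placed = self._donor_with_insert()
        # 60 bp of host followed by 30 bp of the retrocopy start
        s = placed.insert_start - 60
        pair = ReadPair("r", "chrH", s, s + 500, donor["chrH"][s : s + 90], "A" * 90)
        records, truths = oracle_alignments([pair], maps)
        mate1 = [r for r in records if r.flag & 0x40]
        primary = next(r for r in mate1 if not r.flag & 0x800)
        supp = next(r for r in mate1 if r.flag & 0x800)
        assert primary.chrom == "chrH" and primary.cigar == "60M30S"
        assert primary.pos + 60 == placed.bp_left
        assert supp.chrom == "chrG" and supp.cigar == "60S30M"
        assert primary.sa and supp.sa
        assert truths[0].breakpoints == [("chrH", placed.bp_left)]

    def test_end_to_end_breakpoints_recovered_exactly(self, tmp_path):
        from retroscan.evidence import scan_alignments
        from retroscan import build_junction_index

        for orientation in ("forward", "reverse"):
            ref, genes = generate_genome(n_chroms=2, chrom_len=30_000, n_genes=4, seed=12)
            spec = RetrocopySpec(
                "G002", "chr1", 25_000, orientation=orientation, polyA_len=20, tsd_len=4
            )
            sam = tmp_path / f"{orientation}.sam"
            sim = simulate_sample(
                ref, genes, spec, ReadSimParams(error_rate=0.0), depth=80,
                seed=21, out_sam=sam, sample_id="s",
            )
            index = build_junction_index(genes)
            ev = scan_alignments(sam, index)
            anchored = {c.breakpoint for c in ev.clips if not c.unanchored}
            assert anchored == {
                ("chr1", sim.truth.bp_left),
                ("chr1", sim.truth.bp_right),
            }
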