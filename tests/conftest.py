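"""Shared fixtures: toy genes, a small synthetic genome, and one fully
simulated retrocopy sample (built once per session)."""

from __future__ import annotations

import pytest

from retroscan import (
    ReadSimParams,
    RetrocopySpec,
    build_junction_index,
    generate_genome,
    make_gene,
)
from retroscan.pipeline import detect_sample
from retroscan.sim import simulate_sample


@pytest.fixture(scope="session")
def toy_gene():
    """Two-exon '+' gene: exons (100,200) and (300,400) on chr1."""
    return make_gene("g1", "chr1", "+", [(100, 200), (300, 400)])


@pytest.fixture(scope="session")
def toy_index(toy_gene):
    return build_junction_index([toy_gene])


@pytest.fixture(scope="session")
def small_genome():
    """Five 100 kb chromosomes, 20 multi-exon genes."""
    ref, genes = generate_genome(seed=7)
    return ref, genes


@pytest.fixture(scope="session")
def small_index(small_genome):
    _ref, genes = small_genome
    return build_junction_index(genes)


@pytest.fixture(scope="session")
def sim_sample(small_genome, tmp_path_factory):
    """One simulated retrocopy sample (reverse-inserted, TSD 4) with its
    oracle SAM on disk."""
    ref, genes = small_genome
    spec = RetrocopySpec(
        parent_gene_id="G002",
        target_chrom="chr4",
        target_pos=50_000,
        orientation="reverse",
        polyA_len=20,
        tsd_len=4,
    )
    out = tmp_path_factory.mktemp("sim") / "sample.sam"
    sim = simulate_sample(
        ref, genes, spec, ReadSimParams(), depth=100, seed=42, out_sam=out,
        sample_id="s0",
    )
    return sim


@pytest.fixture(scope="session")
def sim_result(sim_sample, small_index):
    return detect_sample(sim_sample.sam_path, small_index, "s0")
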