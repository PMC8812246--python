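"""Simulation benchmark: plant one retrocopy per sample, detect, score.

This reproduces the performance-evaluation design at desk scale: a
synthetic multi-chromosome genome with non-overlapping multi-exon genes,
one randomly placed retrocopy per sample (random parent gene, random
insertion point, TSD 0-11 bp, poly-A 10-30 bp, half of the insertions in
reverse orientation), 90 bp paired reads with 500 bp outer distance and
2% substitution error over the insertion and parent loci, oracle
alignments, then the full detection pipeline and sample-level scoring
with a 500 bp match tolerance.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import build_junction_index
from .calling import SampleResult
from .evaluation import BenchmarkResult, score_samples
from .pipeline import DetectionParams, detect_sample
from .sim import (
    PlacedRetrocopy,
    ReadSimParams,
    RetrocopySpec,
    TruthManifest,
    generate_genome,
    simulate_sample,
)


@dataclass
class BenchmarkConfig:
    n_samples: int = 100
    n_negative: int = 0
    seed: int = 1
    depth: float = 100.0
    tolerance: int = 500
    reverse_fraction: float = 0.5
    tsd_range: tuple[int, int] = (0, 11)
    polya_range: tuple[int, int] = (10, 30)
    n_chroms: int = 5
    chrom_len: int = 100_000
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 8)
    edge_margin: int = 1_000  # keep insertions off chromosome ends
    read_params: ReadSimParams = field(default_factory=ReadSimParams)


def random_specs(
    cfg: BenchmarkConfig, genes, chrom_lens: dict[str, int], rng: np.random.Generator
) -> list[RetrocopySpec]:
    """One spec per positive sample; reverse orientation is assigned by
    stratification (exactly round(fraction*n) reverse, positions shuffled)
    so small batches match the requested fraction exactly."""
    n = cfg.n_samples
    n_rev = int(round(cfg.reverse_fraction * n))
    orient = np.array(["forward"] * (n - n_rev) + ["reverse"] * n_rev)
    rng.shuffle(orient)
    chroms = list(chrom_lens)
    specs = []
    for i in range(n):
        parent = genes[int(rng.integers(0, len(genes)))]
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(cfg.edge_margin, chrom_lens[chrom] - cfg.edge_margin))
        specs.append(
            RetrocopySpec(
                parent_gene_id=parent.gene_id,
                target_chrom=chrom,
                target_pos=pos,
                orientation=str(orient[i]),
                polyA_len=int(rng.integers(cfg.polya_range[0], cfg.polya_range[1] + 1)),
                tsd_len=int(rng.integers(cfg.tsd_range[0], cfg.tsd_range[1] + 1)),
            )
        )
    return specs


def run_benchmark(
    cfg: BenchmarkConfig,
    workdir: str | Path | None = None,
    params: DetectionParams | None = None,
    keep_files: bool = False,
) -> tuple[BenchmarkResult, list[tuple[SampleResult, PlacedRetrocopy | None]], TruthManifest]:
    """Run the full simulate -> detect -> score loop.

    Returns the aggregate confusion result, the per-sample (calls, truth)
    pairs and the truth manifest.  All randomness derives from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    ref, genes = generate_genome(
        n_chroms=cfg.n_chroms,
        chrom_len=cfg.chrom_len,
        n_genes=cfg.n_genes,
        exons_per_gene_range=cfg.exons_per_gene,
        seed=int(rng.integers(0, 2**31)),
    )
    chrom_lens = {c: len(s) for c, s in ref.items()}
    index = build_junction_index(genes)
    params = params or DetectionParams()
    specs = random_specs(cfg, genes, chrom_lens, rng)

    own_tmp = None
    if workdir is None:
        own_tmp = tempfile.TemporaryDirectory(prefix="retroscan-bench-")
        workdir = own_tmp.name
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    pairs: list[tuple[SampleResult, PlacedRetrocopy | None]] = []
    manifest = TruthManifest()
    try:
        for i, spec in enumerate(specs):
            sid = f"s{i:04d}"
            sam = workdir / f"{sid}.sam"
            sim = simulate_sample(
                ref,
                genes,
                spec,
                cfg.read_params,
                depth=cfg.depth,
                seed=int(rng.integers(0, 2**31)),
                out_sam=sam,
                sample_id=sid,
            )
            result = detect_sample(sam, index, sid, params)
            pairs.append((result, sim.truth))
            manifest.entries.append(sim.truth)
            if not keep_files:
                sam.unlink()
        for i in range(cfg.n_negative):
            sid = f"n{i:04d}"
            sam = workdir / f"{sid}.sam"
            sim = simulate_sample(
                ref,
                genes,
                None,
                cfg.read_params,
                depth=cfg.depth,
                seed=int(rng.integers(0, 2**31)),
                out_sam=sam,
                sample_id=sid,
            )
            result = detect_sample(sam, index, sid, params)
            pairs.append((result, None))
            if not keep_files:
                sam.unlink()
    finally:
        if own_tmp is not None:
            own_tmp.cleanup()
    return score_samples(pairs, cfg.tolerance), pairs, manifest
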