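"""End-to-end detection: annotation -> evidence scan -> calling -> reports."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import (
    JunctionIndex,
    KnownPsgCatalog,
    build_junction_index,
    read_gene_annotation,
    read_known_psg_bed,
)
from .calling import CallParams, SampleResult, call_sample
from .evidence import ScanParams, scan_alignments
from .report import write_html, write_sites_bed, write_tsv

logger = logging.getLogger("retroscan")


@dataclass
class DetectionParams:
    """All detection tunables with their documented defaults."""

    min_mapq: int = 20
    slack: int = 0
    max_concordant_distance: int = 10_000
    min_clip: int = 20
    locus_pad: int = 500
    min_sr: int = 3
    min_junctions: int = 1
    window: int = 500

    @property
    def scan(self) -> ScanParams:
        return ScanParams(
            min_mapq=self.min_mapq,
            slack=self.slack,
            max_concordant_distance=self.max_concordant_distance,
            min_clip=self.min_clip,
            locus_pad=self.locus_pad,
        )

    @property
    def call(self) -> CallParams:
        return CallParams(
            min_sr=self.min_sr, min_junctions=self.min_junctions, window=self.window
        )


def detect_sample(
    aln_path: str | Path,
    index: JunctionIndex,
    sample_id: str = "sample",
    params: DetectionParams | None = None,
    catalog: KnownPsgCatalog | None = None,
) -> SampleResult:
    """Scan one alignment file against a prebuilt junction index."""
    params = params or DetectionParams()
    t0 = time.perf_counter()
    ev = scan_alignments(aln_path, index, params.scan)
    t1 = time.perf_counter()
    result = call_sample(ev, index, sample_id, params.call, catalog)
    logger.info(
        "%s: %d reads scanned (%.2fs), SR=%d CP=%d CR=%d -> %d candidates, %d sites (%.2fs)",
        sample_id,
        ev.reads_seen,
        t1 - t0,
        len(ev.spliced),
        len(ev.pairs),
        len(ev.clips),
        len(result.candidates),
        len(result.sites),
        time.perf_counter() - t1,
    )
    return result


def run_detection(
    aln_path: str | Path,
    annotation_path: str | Path,
    out_dir: str | Path | None = None,
    known_psg_bed: str | Path | None = None,
    sample_id: str | None = None,
    params: DetectionParams | None = None,
) -> SampleResult:
    """File-level entry point: read the annotation (and optional known
    pseudogene catalog), scan the alignments and, when ``out_dir`` is
    given, write the TSV/HTML reports and a BED of called sites."""
    params = params or DetectionParams()
    sample_id = sample_id or Path(aln_path).stem
    genes = read_gene_annotation(annotation_path)
    if not genes:
        raise ValueError(f"no genes read from {annotation_path}")
    index = build_junction_index(genes)
    catalog = read_known_psg_bed(known_psg_bed) if known_psg_bed else None
    result = detect_sample(aln_path, index, sample_id, params, catalog)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n_junc = {g: index.n_junctions(g) for g in index.genes}
        write_tsv([result], out / f"{sample_id}.report.tsv", n_junc)
        write_html([result], out / f"{sample_id}.report.html", n_junctions=n_junc)
        write_sites_bed([result], out / f"{sample_id}.sites.bed")
    return result
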