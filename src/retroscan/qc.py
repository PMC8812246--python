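"""Coverage-based detection-level QC and read downsampling.

Insertion-site calls lose evidence classes as sequencing depth drops.
The operational rule, applied to mean coverage over the target regions:
>= 144X is confident, <= 95X is below the detection level, and the band
in between is a gray zone whose predictions deserve manual inspection.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger("retroscan")

CONFIDENT_MIN_X = 144.0
BELOW_MAX_X = 95.0


@dataclass
class CoverageSummary:
    sample_id: str
    mean_coverage: float
    n_read_pairs: int
    tier: str | None = None  # 'confident' | 'gray_zone' | 'below_detection'


def mean_target_coverage(
    aln_path: str | Path,
    targets: list[tuple[str, int, int]],
    sample_id: str = "sample",
) -> CoverageSummary:
    """Mean per-base depth of primary, non-duplicate reads over all target
    bases (bases with zero coverage included)."""
    if not targets:
        raise ValueError("target set is empty")
    depth = {i: np.zeros(end - start, dtype=np.int32) for i, (_, start, end) in enumerate(targets)}
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, _s, _e) in enumerate(targets):
        by_chrom.setdefault(chrom, []).append(i)
    names: set[str] = set()
    with pysam.AlignmentFile(str(aln_path), check_sq=False) as aln:
        for rec in aln:
            if (
                rec.is_unmapped
                or rec.is_secondary
                or rec.is_supplementary
                or rec.is_duplicate
            ):
                continue
            names.add(rec.query_name)
            for i in by_chrom.get(rec.reference_name, ()):
                _c, t_start, t_end = targets[i]
                for b_start, b_end in rec.get_blocks():
                    lo, hi = max(b_start, t_start), min(b_end, t_end)
                    if lo < hi:
                        depth[i][lo - t_start : hi - t_start] += 1
    total_bases = sum(arr.size for arr in depth.values())
    total_depth = sum(int(arr.sum()) for arr in depth.values())
    return CoverageSummary(
        sample_id=sample_id,
        mean_coverage=total_depth / total_bases,
        n_read_pairs=len(names),
    )


def classify_confidence(
    cov: CoverageSummary,
    confident_min: float = CONFIDENT_MIN_X,
    below_max: float = BELOW_MAX_X,
) -> CoverageSummary:
    """Assign the detection tier from mean coverage (thresholds in X)."""
    if not confident_min > below_max:
        raise ValueError("confident_min must exceed below_max")
    if cov.mean_coverage >= confident_min:
        cov.tier = "confident"
    elif cov.mean_coverage <= below_max:
        cov.tier = "below_detection"
    else:
        cov.tier = "gray_zone"
    return cov


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------


def _read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    records = []
    with open(path) as fh:
        while True:
            head = fh.readline().rstrip("\n")
            if not head:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            records.append((head, seq, qual))
    return records


def downsample_pairs(
    fq1: str | Path,
    fq2: str | Path,
    n_pairs: int,
    seed: int,
    out1: str | Path,
    out2: str | Path,
) -> None:
    """Uniform mate-paired sampling without replacement, reproducible for
    a fixed seed.  Input order is preserved in the output."""
    r1 = _read_fastq(fq1)
    r2 = _read_fastq(fq2)
    if len(r1) != len(r2):
        raise ValueError(f"mate files differ in length: {len(r1)} vs {len(r2)}")
    if n_pairs > len(r1):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(r1)} are available"
        )
    rng = random.Random(seed)
    keep = sorted(rng.sample(range(len(r1)), n_pairs))
    with open(out1, "w") as f1, open(out2, "w") as f2:
        for i in keep:
            h, s, q = r1[i]
            f1.write(f"{h}\n{s}\n+\n{q}\n")
            h, s, q = r2[i]
            f2.write(f"{h}\n{s}\n+\n{q}\n")


def downsample_alignments(
    sam_in: str | Path, n_pairs: int, seed: int, sam_out: str | Path
) -> set[str]:
    """Sample read names (pairs) from an alignment file and write the
    filtered file; returns the retained name set."""
    with pysam.AlignmentFile(str(sam_in), check_sq=False) as aln:
        names = sorted({rec.query_name for rec in aln})
    if n_pairs > len(names):
        raise ValueError(
            f"requested {n_pairs} pairs but only {len(names)} are available"
        )
    rng = random.Random(seed)
    keep = set(rng.sample(names, n_pairs))
    with pysam.AlignmentFile(str(sam_in), check_sq=False) as aln:
        with pysam.AlignmentFile(str(sam_out), "wh", template=aln) as out:
            for rec in aln:
                if rec.query_name in keep:
                    out.write(rec)
    return keep
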