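"""Scoring predictions against simulator truth.

A simulated sample carries at most one planted insertion, so scoring is
sample-level: a sample is a true positive when any called site for the
true parent gene falls within the match tolerance of the true breakpoint;
negative-control samples with no calls are true negatives.  Site-level
false positives (called sites matching no truth) are also counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .calling import InsertionSite, SampleResult
from .sim import PlacedRetrocopy


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def tpr(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def fdr(self) -> float | None:
        p = self.ppv
        return None if p is None else 1.0 - p

    @property
    def f1(self) -> float | None:
        p, t = self.ppv, self.tpr
        if p is None or t is None or (p + t) == 0:
            return None
        return 2 * p * t / (p + t)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "tpr": self.tpr,
            "ppv": self.ppv,
            "fdr": self.fdr,
            "f1": self.f1,
        }

    def write_tsv(self, path: str | Path) -> None:
        d = self.as_dict()
        with open(path, "w") as out:
            out.write("\t".join(d) + "\n")
            out.write(
                "\t".join("NA" if v is None else str(v) for v in d.values()) + "\n"
            )


def match_site(
    pred: InsertionSite, truth: PlacedRetrocopy, tolerance: int = 500
) -> bool:
    """True iff the parent genes agree and the predicted interval, expanded
    by ``tolerance`` (and by its CP-only cluster span when present),
    overlaps the true insertion point."""
    if pred.gene_id != truth.parent_gene_id and pred.gene_name != truth.parent_gene_name:
        return False
    if pred.chrom != truth.chrom:
        return False
    start, end = pred.start, pred.end
    if "cluster_span" in pred.metadata:
        cs = pred.metadata["cluster_span"]
        start, end = min(start, cs[0]), max(end, cs[1])
    return start - tolerance <= truth.pos < end + tolerance


def score_samples(
    results: list[tuple[SampleResult, PlacedRetrocopy | None]],
    tolerance: int = 500,
) -> BenchmarkResult:
    """Aggregate sample-level confusion counts.

    ``results`` pairs each sample's calls with its truth entry (None for a
    negative control).  Raises on duplicated sample ids.
    """
    seen: set[str] = set()
    tp = fp = fn = tn = 0
    for res, truth in results:
        if res.sample_id in seen:
            raise ValueError(f"duplicate sample id {res.sample_id}")
        seen.add(res.sample_id)
        if truth is not None and res.sample_id != truth.sample_id:
            raise ValueError(
                f"sample id mismatch: {res.sample_id} vs {truth.sample_id}"
            )
        if truth is None or not truth.parent_gene_id:
            if res.sites:
                fp += len(res.sites)
            else:
                tn += 1
            continue
        matched = [s for s in res.sites if match_site(s, truth, tolerance)]
        if matched:
            tp += 1
        else:
            fn += 1
        fp += sum(1 for s in res.sites if not match_site(s, truth, tolerance))
    return BenchmarkResult(tp=tp, fp=fp, fn=fn, tn=tn)
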