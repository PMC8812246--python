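"""User-facing outputs: sortable TSV report, self-contained HTML summary,
locus plots (linear or circular) and the detection-level scatter.

Display coordinates are 1-based inclusive (``chr9:127732713-127732715``
style); BED exports stay 0-based half-open.  The HTML page is rendered
from the same row table the TSV contains, so every numeric cell in it is
re-derivable from the TSV.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .annotation import GeneModel
from .calling import InsertionSite, PsgCandidate, SampleResult
from .qc import CoverageSummary

TSV_COLUMNS = [
    "sample_id",
    "parent_gene",
    "sr_count",
    "junctions",
    "site",
    "tier",
    "cp_count",
    "cr_count",
    "feature",
    "host_gene",
    "host_rank",
    "orientation",
    "known",
]

TIERS = ["CP-CR", "CP", "CR"]
REGIONS = ["exonic", "intronic", "intergenic"]


def _display_site(site: InsertionSite) -> str:
    return f"{site.chrom}:{site.start + 1}-{site.end}"


def parse_display_site(text: str) -> tuple[str, int, int]:
    """Invert the 1-based inclusive display form back to 0-based half-open."""
    chrom, rest = text.rsplit(":", 1)
    lo, hi = rest.split("-")
    return chrom, int(lo) - 1, int(hi)


def build_rows(
    results: list[SampleResult], n_junctions: dict[str, int] | None = None
) -> pd.DataFrame:
    """One row per (candidate, site); candidates without sites keep a row
    with empty site fields.  Sorted by (sample, gene, site)."""
    rows: list[list[str]] = []
    for res in results:
        sites_by_gene: dict[str, list[InsertionSite]] = {}
        for s in res.sites:
            sites_by_gene.setdefault(s.gene_id, []).append(s)
        for cand in sorted(res.candidates, key=lambda c: c.gene_id):
            if n_junctions:
                total = n_junctions[cand.gene_id]
            elif cand.fraction_junctions_covered:
                total = round(cand.distinct_junctions / cand.fraction_junctions_covered)
            else:
                total = cand.distinct_junctions
            junctions = f"{cand.distinct_junctions}/{total}"
            gene_sites = sorted(
                sites_by_gene.get(cand.gene_id, []), key=lambda s: (s.chrom, s.start)
            )
            if not gene_sites:
                rows.append(
                    [res.sample_id, cand.gene_name, str(cand.total_sr), junctions]
                    + [""] * 9
                )
            for s in gene_sites:
                rows.append(
                    [
                        res.sample_id,
                        cand.gene_name,
                        str(cand.total_sr),
                        junctions,
                        _display_site(s),
                        s.tier,
                        str(s.cp_count),
                        str(s.cr_count),
                        s.feature,
                        s.host_gene or "",
                        "" if s.host_rank is None else str(s.host_rank),
                        s.orientation,
                        "known" if s.known else "novel",
                    ]
                )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS, dtype=str)
    return df.sort_values(["sample_id", "parent_gene", "site"], kind="stable").reset_index(
        drop=True
    )


def write_tsv(
    results: list[SampleResult],
    path: str | Path,
    n_junctions: dict[str, int] | None = None,
) -> pd.DataFrame:
    df = build_rows(results, n_junctions)
    df.to_csv(path, sep="\t", index=False)
    return df


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_sites_bed(results: list[SampleResult], path: str | Path) -> None:
    with open(path, "w") as out:
        for res in results:
            for s in sorted(res.sites, key=lambda s: (s.chrom, s.start)):
                out.write(
                    f"{s.chrom}\t{s.start}\t{s.end}\t"
                    f"{res.sample_id}:{s.gene_name}:{s.tier}\n"
                )


# ---------------------------------------------------------------------------
# html summary
# ---------------------------------------------------------------------------

_CSS = """
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 4px 10px; text-align: left; }
th { background: #e8eef7; }
caption { font-weight: bold; text-align: left; padding: 4px 0; }
"""


def summary_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Gene x (region x tier) counts of called sites, recounted from the
    report rows (rows with empty site fields are not sites)."""
    cols = pd.MultiIndex.from_tuples(
        [(r, t) for r in REGIONS for t in TIERS], names=["region", "tier"]
    )
    called = df[df["site"] != ""]
    genes = sorted(called["parent_gene"].unique())
    data = []
    for g in genes:
        sub = called[called["parent_gene"] == g]
        data.append(
            [
                int(((sub["feature"] == r) & (sub["tier"] == t)).sum())
                for r in REGIONS
                for t in TIERS
            ]
        )
    return pd.DataFrame(data, index=genes, columns=cols, dtype=int)


def _render_html(df: pd.DataFrame, path: str | Path, metrics: dict | None = None) -> None:
    matrix = summary_matrix(df)
    n_samples = df["sample_id"].nunique()
    n_sites = int((df["site"] != "").sum())
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>retroscan report</title>",
        f"<style>{_CSS}</style></head><body>",
        "<h1>Processed-pseudogene detection report</h1>",
        f"<p>{n_samples} sample(s), {n_sites} called insertion site(s).</p>",
        "<table><caption>Insertion sites by region and evidence tier</caption>",
        "<tr><th rowspan='2'>Gene</th>"
        + "".join(f"<th colspan='3'>{html.escape(r)}</th>" for r in REGIONS)
        + "</tr><tr>"
        + "".join(f"<th>{t}</th>" for _ in REGIONS for t in TIERS)
        + "</tr>",
    ]
    if len(matrix):
        for gene, row in matrix.iterrows():
            parts.append(
                f"<tr><td>{html.escape(str(gene))}</td>"
                + "".join(f"<td>{int(v)}</td>" for v in row)
                + "</tr>"
            )
    else:
        parts.append("<tr><td>-</td>" + "<td>0</td>" * (len(REGIONS) * len(TIERS)) + "</tr>")
    parts.append("</table>")

    for label, mask in (
        ("Novel", df["known"] != "known"),
        ("Known", df["known"] == "known"),
    ):
        sub = df[mask]
        parts.append(f"<table><caption>{label} calls</caption>")
        parts.append("<tr>" + "".join(f"<th>{c}</th>" for c in TSV_COLUMNS) + "</tr>")
        for _, r in sub.iterrows():
            parts.append(
                "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in r) + "</tr>"
            )
        parts.append("</table>")

    if metrics:
        parts.append("<table><caption>Benchmark metrics</caption><tr>")
        parts.append("".join(f"<th>{html.escape(k)}</th>" for k in metrics))
        parts.append("</tr><tr>")
        parts.append(
            "".join(
                f"<td>{'NA' if v is None else (f'{v:.4f}' if isinstance(v, float) else v)}</td>"
                for v in metrics.values()
            )
        )
        parts.append("</tr></table>")
    parts.append("</body></html>")
    Path(path).write_text("".join(parts))


def write_html(
    results: list[SampleResult],
    path: str | Path,
    metrics: dict | None = None,
    n_junctions: dict[str, int] | None = None,
) -> None:
    _render_html(build_rows(results, n_junctions), path, metrics)


def write_html_from_tsv(tsv_path: str | Path, path: str | Path, metrics: dict | None = None) -> None:
    _render_html(read_tsv(tsv_path), path, metrics)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------


def plot_locus(
    parent: GeneModel,
    candidate: PsgCandidate,
    site: InsertionSite | None,
    exon_coverage: list[float],
    site_coverage: np.ndarray | None,
    path: str | Path,
    layout: str = "linear",
) -> None:
    """Parent-gene/insertion-site figure: exon coverage heat, junction
    spliced-read histogram, and (when a site exists) coverage across the
    insertion neighbourhood with a link back to the parent gene.

    ``layout='circular'`` renders the same three tracks on a polar axis.
    """
    exons = parent.canonical_transcript.exons
    jx = [c for _d, _a, c in candidate.junctions_supported]
    if layout == "circular":
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(111, projection="polar")
        n = len(exons)
        theta = np.linspace(0.1, 1.9 * np.pi, n, endpoint=True)
        cov = np.asarray(exon_coverage, dtype=float)
        vmax = cov.max() if cov.size and cov.max() > 0 else 1.0
        ax.bar(theta, np.ones(n) * 0.15, width=1.5 / max(n, 1), bottom=1.0,
               color=plt.cm.Blues(0.25 + 0.75 * cov / vmax))
        if jx:
            jtheta = (theta[:-1] + theta[1:]) / 2 if n > 1 else theta
            jn = np.asarray(jx, dtype=float)
            ax.bar(jtheta[: len(jn)], 0.6 * jn / jn.max(), width=0.8 / max(n, 1),
                   bottom=0.3, color="steelblue")
        if site is not None and site_coverage is not None and len(site_coverage):
            sc = np.asarray(site_coverage, dtype=float)
            stheta = np.linspace(0, 0.4, sc.size) + 2.0 * np.pi - 0.45
            ax.bar(stheta, 0.25 * sc / max(sc.max(), 1.0), width=0.45 / sc.size,
                   bottom=1.25, color="firebrick")
            ax.annotate("", xy=(stheta[sc.size // 2], 1.2), xytext=(theta[n // 2], 1.0),
                        arrowprops=dict(arrowstyle="->", color="gray"))
        ax.set_rlim(0, 1.6)
        ax.set_xticks([])
        ax.set_yticks([])
        title = parent.gene_name
        if site is not None:
            title += f" insertion {_display_site(site)}"
        ax.set_title(title)
    else:
        n_panels = 3 if site is not None else 2
        fig, axes = plt.subplots(n_panels, 1, figsize=(8, 2.2 * n_panels))
        axes = np.atleast_1d(axes)
        cov = np.asarray(exon_coverage, dtype=float)
        vmax = cov.max() if cov.size and cov.max() > 0 else 1.0
        for e, c in zip(exons, cov):
            axes[0].axvspan(e.start, e.end, color=plt.cm.Blues(0.25 + 0.75 * c / vmax))
        axes[0].set_xlim(exons[0].start - 100, exons[-1].end + 100)
        axes[0].set_yticks([])
        axes[0].set_ylabel("exon cov")
        axes[0].set_title(f"{parent.gene_name} ({parent.chrom}, {parent.strand})")
        axes[1].bar(range(1, len(jx) + 1), jx, color="steelblue")
        axes[1].set_ylabel("SR / junction")
        axes[1].set_xlabel("junction (transcription order)")
        if site is not None:
            sc = (
                np.asarray(site_coverage, dtype=float)
                if site_coverage is not None
                else np.zeros(1)
            )
            x = np.arange(sc.size) + site.start - sc.size // 2
            axes[2].fill_between(x, sc, color="firebrick", alpha=0.7)
            axes[2].axvline(site.start, color="k", ls="--", lw=0.8)
            axes[2].set_ylabel("site cov")
            axes[2].set_xlabel(f"{_display_site(site)} [{site.tier}]")
        fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def plot_detection_scatter(
    coverages: list[CoverageSummary],
    site_counts: list[int],
    path: str | Path,
    confident_min: float = 144.0,
    below_max: float = 95.0,
) -> None:
    """Mean coverage vs number of predicted sites with the detection-level
    thresholds drawn as dashed lines."""
    if not coverages:
        raise ValueError("need at least one sample")
    fig, ax = plt.subplots(figsize=(6, 4))
    x = [c.mean_coverage for c in coverages]
    ax.scatter(x, site_counts, color="firebrick", zorder=3)
    ax.axvline(confident_min, color="gray", ls="--", label=f"confident >= {confident_min:g}X")
    ax.axvline(below_max, color="red", ls="--", label=f"below detection <= {below_max:g}X")
    ax.set_xlabel("mean target coverage (X)")
    ax.set_ylabel("predicted insertion sites")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
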