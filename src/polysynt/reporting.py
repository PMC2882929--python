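"""End-to-end pipeline reports mirroring the study's summary arithmetic.

Gene statistics, clone-table fractions, rearrangement class totals, repeat
accounting and the molecular-clock estimate are assembled into TSV tables
plus a human-readable summary.  Every percentage printed is recomputable
from raw columns that are also present in the report (self-consistency),
and identical inputs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io_formats import format_pct, write_tsv_report
from .kaks_divergence import DivergenceEstimate
from .rearrangement_synteny import RearrangementSummary
from .repeats_ssr import RepeatSummary
from .template_scaffolding import SyntenySummary


@dataclass
class GeneStats:
    n_genes_query: int
    n_genes_template: int
    n_orthologs: int
    n_query_specific: int
    n_template_specific: int
    n_validated: int
    insert_kb: float
    gene_density_kb_per_gene: float
    ortholog_fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "n_genes_query": self.n_genes_query,
                    "n_genes_template": self.n_genes_template,
                    "n_orthologs": self.n_orthologs,
                    "n_query_specific": self.n_query_specific,
                    "n_template_specific": self.n_template_specific,
                    "n_validated": self.n_validated,
                    "insert_kb": self.insert_kb,
                    "gene_density_kb_per_gene": self.gene_density_kb_per_gene,
                    "ortholog_pct": round(100 * self.ortholog_fraction, 1),
                }
            ]
        )


def compute_gene_stats(
    n_genes_query: int,
    n_genes_template: int,
    n_orthologs: int,
    n_query_specific: int,
    n_template_specific: int,
    n_validated: int,
    insert_kb: float,
) -> GeneStats:
    """Gene-content accounting: density uses the validated gene count.

    density (kb/gene) = insert_kb / validated genes, rounded to one decimal;
    ortholog fraction = orthologs / query genes.
    """
    if n_orthologs > min(n_genes_query, n_genes_template):
        raise ValueError("more orthologs than genes on one side")
    if n_validated <= 0:
        raise ValueError("zero validated genes; density undefined")
    return GeneStats(
        n_genes_query=n_genes_query,
        n_genes_template=n_genes_template,
        n_orthologs=n_orthologs,
        n_query_specific=n_query_specific,
        n_template_specific=n_template_specific,
        n_validated=n_validated,
        insert_kb=insert_kb,
        gene_density_kb_per_gene=round(insert_kb / n_validated, 1),
        ortholog_fraction=n_orthologs / n_genes_query,
    )


@dataclass
class PipelineReport:
    synteny: SyntenySummary | None = None
    rearrangements: RearrangementSummary | None = None
    repeats_query: RepeatSummary | None = None
    repeats_template: RepeatSummary | None = None
    divergence: DivergenceEstimate | None = None
    gene_stats: GeneStats | None = None
    caveats: list[str] = field(
        default_factory=lambda: [
            "Inversion polarity is reported relative to the template; without "
            "an outgroup the genome of origin cannot be inferred.",
            "Indel events are not enumerated in the rearrangement table; they "
            "are reflected only in unaligned bp.",
        ]
    )


def render_report(report: PipelineReport, out_dir) -> list[str]:
    """Write TSV tables and a Markdown summary; returns the files written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    lines: list[str] = ["# Microsynteny pipeline report", ""]

    if report.synteny is not None:
        s = report.synteny
        write_tsv_report(s.per_clone, out / "clone_summary.tsv")
        written.append("clone_summary.tsv")
        lines += [
            "## Template-guided ordering",
            f"- insert total: {s.insert_bp} bp; ordered contig total: {s.ordered_bp} bp "
            f"({format_pct(100 * s.ordered_fraction)})",
            f"- aligned (spanned) query bp: {s.spanned_query_bp} "
            f"({format_pct(100 * s.aligned_fraction)} of inserts)",
            f"- spanned template bp: {s.spanned_template_bp} "
            f"(template expansion {format_pct(100 * s.expansion_fraction)})",
            "",
        ]
    if report.rearrangements is not None:
        write_tsv_report(report.rearrangements.table, out / "rearrangements.tsv")
        written.append("rearrangements.tsv")
        lines += ["## Rearrangements", report.rearrangements.table.to_string(index=False), ""]
    for label, summary in (
        ("query", report.repeats_query),
        ("template", report.repeats_template),
    ):
        if summary is not None:
            write_tsv_report(summary.to_dataframe(), out / f"repeats_{label}.tsv")
            written.append(f"repeats_{label}.tsv")
            lines += [
                f"## Repeats ({label})",
                f"- masked {summary.masked_bp} of {summary.total_sequence_bp} bp "
                f"({format_pct(100 * summary.fraction(summary.masked_bp))})",
                "",
            ]
    if report.gene_stats is not None:
        g = report.gene_stats
        write_tsv_report(g.to_dataframe(), out / "gene_stats.tsv")
        written.append("gene_stats.tsv")
        lines += [
            "## Gene content",
            f"- {g.n_genes_query} query genes, {g.n_genes_template} template genes, "
            f"{g.n_orthologs} orthologs ({format_pct(100 * g.ortholog_fraction)})",
            f"- {g.n_query_specific} query-specific, {g.n_template_specific} "
            "template-specific genes (relative to the aligned counterpart "
            "interval only)",
            f"- gene density: one gene / {g.gene_density_kb_per_gene} kb "
            f"({g.n_validated} validated genes over {g.insert_kb} kb)",
            "",
        ]
    if report.divergence is not None:
        d = report.divergence
        df = pd.DataFrame(
            [
                {
                    "median_ks": d.median_ks,
                    "n_pairs": d.n_pairs,
                    "rate_per_site_per_year": d.rate,
                    "divergence_time_mya": d.time_mya,
                }
            ]
        )
        write_tsv_report(df, out / "divergence.tsv")
        written.append("divergence.tsv")
        lines += [
            "## Divergence dating",
            f"- median Ks {d.median_ks} over {d.n_pairs} ortholog pairs; "
            f"T = Ks / (2 x {d.rate:g}) = {d.time_mya} MYa",
            "",
        ]
    if report.caveats:
        lines += ["## Caveats"] + [f"- {c}" for c in report.caveats] + [""]
    (out / "summary.md").write_text("\n".join(lines))
    written.append("summary.md")
    return written


def audit_self_consistency(report: PipelineReport) -> bool:
    """Check every derived fraction against its raw columns."""
    ok = True
    if report.synteny is not None:
        s = report.synteny
        ok &= abs(s.ordered_fraction - s.ordered_bp / s.insert_bp) < 1e-9
        ok &= abs(s.aligned_fraction - s.spanned_query_bp / s.insert_bp) < 1e-9
        if s.spanned_query_bp:
            ok &= (
                abs(
                    s.expansion_fraction
                    - (s.spanned_template_bp - s.spanned_query_bp) / s.spanned_query_bp
                )
                < 1e-9
            )
    if report.rearrangements is not None:
        t = report.rearrangements.table
        body = t[t["event_class"] != "Total"]
        total = t[t["event_class"] == "Total"].iloc[0]
        ok &= int(body["n_events"].sum()) == int(total["n_events"])
        ok &= int(body["total_bp"].sum()) == int(total["total_bp"])
        for _, row in t.iterrows():
            if row["n_events"]:
                ok &= row["mean_bp"] == round(row["total_bp"] / row["n_events"])
    if report.gene_stats is not None:
        g = report.gene_stats
        ok &= g.gene_density_kb_per_gene == round(g.insert_kb / g.n_validated, 1)
        ok &= abs(g.ortholog_fraction - g.n_orthologs / g.n_genes_query) < 1e-9
    if report.divergence is not None:
        d = report.divergence
        ok &= d.time_mya == round(d.median_ks / (2 * d.rate) / 1e6, 1)
    return bool(ok)
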