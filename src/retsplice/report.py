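"""Study-level summary: aggregate stage outputs and render the derived
bookkeeping (totals, percentages) from raw counts.

Every derived number is computed from the raw counts in the same summary;
a self-consistency check re-derives them independently and raises on any
mismatch. Percentages are rounded half-up to integer precision.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Dict, Optional

import pandas as pd

from .model import RetspliceError


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    return float(d) if ndigits > 0 else int(d)


@dataclass
class AlignmentStats:
    total_reads: int
    uniquely_aligned: int
    non_uniquely_aligned: int

    @property
    def total_aligned(self) -> int:
        return self.uniquely_aligned + self.non_uniquely_aligned

    @property
    def pct_unique(self) -> int:
        return round_half_up(100.0 * self.uniquely_aligned / self.total_reads)

    @property
    def pct_non_unique(self) -> int:
        return round_half_up(100.0 * self.non_uniquely_aligned / self.total_reads)

    @property
    def pct_aligned(self) -> int:
        return round_half_up(100.0 * self.total_aligned / self.total_reads)


@dataclass
class StudySummary:
    # per-class event counts
    n_novel_exons: int = 0  # internal + terminal combined
    n_internal_exons: int = 0
    n_terminal_exons: int = 0
    n_skips: int = 0
    n_alt_sites: int = 0
    n_alt3: int = 0
    n_alt5: int = 0
    # frame breakdown percentages (per class, label -> pct)
    frame_pct: Dict[str, Dict[str, float]] = field(default_factory=dict)
    # novel genes
    n_novel_genes: int = 0
    n_coding_genes: int = 0
    n_lincrna_genes: int = 0
    # alt-site sequence bookkeeping
    added_bp: int = 0
    removed_bp: int = 0
    # reference context
    n_reference_exons: int = 0
    n_reference_transcripts: int = 0
    # junction read totals
    annotated_junction_reads: int = 0
    novel_junction_reads: int = 0
    alignment: Optional[AlignmentStats] = None

    # -- derived --------------------------------------------------------

    @property
    def total_novel_events(self) -> int:
        return self.n_novel_exons + self.n_skips + self.n_alt_sites

    @property
    def novel_exon_pct_of_reference(self) -> float:
        if not self.n_reference_exons:
            return 0.0
        return 100.0 * self.n_novel_exons / self.n_reference_exons

    @property
    def annotated_novel_read_fold(self) -> float:
        if not self.novel_junction_reads:
            return float("inf") if self.annotated_junction_reads else 0.0
        return self.annotated_junction_reads / self.novel_junction_reads


def summarize_study(event_counts: Dict[str, int],
                    frame_pct: Optional[Dict[str, Dict[str, float]]] = None,
                    gene_counts: Optional[Dict[str, int]] = None,
                    sequence_bp: Optional[Dict[str, int]] = None,
                    reference_counts: Optional[Dict[str, int]] = None,
                    junction_reads: Optional[Dict[str, int]] = None,
                    alignment_stats: Optional[Dict[str, int]] = None
                    ) -> StudySummary:
    """Assemble a :class:`StudySummary` from stage outputs.

    ``event_counts`` requires keys novel_exon_internal, novel_exon_terminal,
    exon_skip, alt3, alt5; derived totals (novel exon total, alt-site
    total, study total) are computed, never re-entered. Raises on
    internally inconsistent inputs (e.g. alt3 + alt5 totals that disagree
    with a supplied alt_site count).
    """
    required = {"novel_exon_internal", "novel_exon_terminal", "exon_skip",
                "alt3", "alt5"}
    missing = required - set(event_counts)
    if missing:
        raise RetspliceError(f"missing event counts: {sorted(missing)}")
    if "alt_site" in event_counts and (
            event_counts["alt_site"]
            != event_counts["alt3"] + event_counts["alt5"]):
        raise RetspliceError("alt_site total disagrees with alt3 + alt5")
    summary = StudySummary(
        n_internal_exons=event_counts["novel_exon_internal"],
        n_terminal_exons=event_counts["novel_exon_terminal"],
        n_novel_exons=(event_counts["novel_exon_internal"]
                       + event_counts["novel_exon_terminal"]),
        n_skips=event_counts["exon_skip"],
        n_alt3=event_counts["alt3"],
        n_alt5=event_counts["alt5"],
        n_alt_sites=event_counts["alt3"] + event_counts["alt5"],
        frame_pct=frame_pct or {},
    )
    if gene_counts:
        summary.n_novel_genes = gene_counts.get("total", 0)
        summary.n_coding_genes = gene_counts.get("protein_coding", 0)
        summary.n_lincrna_genes = gene_counts.get("lincRNA_candidate", 0)
        if (summary.n_coding_genes + summary.n_lincrna_genes
                not in (0, summary.n_novel_genes)):
            raise RetspliceError("novel-gene coding split disagrees with total")
    if sequence_bp:
        summary.added_bp = sequence_bp.get("added", 0)
        summary.removed_bp = sequence_bp.get("removed", 0)
    if reference_counts:
        summary.n_reference_exons = reference_counts.get("exons", 0)
        summary.n_reference_transcripts = reference_counts.get("transcripts", 0)
    if junction_reads:
        summary.annotated_junction_reads = junction_reads.get("annotated", 0)
        summary.novel_junction_reads = junction_reads.get("novel", 0)
    if alignment_stats:
        summary.alignment = AlignmentStats(
            total_reads=alignment_stats["total_reads"],
            uniquely_aligned=alignment_stats["uniquely_aligned"],
            non_uniquely_aligned=alignment_stats["non_uniquely_aligned"])
    check_consistency(summary)
    return summary


def check_consistency(summary: StudySummary) -> None:
    """Re-derive every derived field from the raw counts; raise on mismatch."""
    if summary.total_novel_events != (
            summary.n_novel_exons + summary.n_skips + summary.n_alt_sites):
        raise RetspliceError("total_novel_events inconsistent")
    if summary.n_novel_exons != summary.n_internal_exons + summary.n_terminal_exons:
        raise RetspliceError("novel exon split inconsistent")
    if summary.n_alt_sites != summary.n_alt3 + summary.n_alt5:
        raise RetspliceError("alt-site split inconsistent")
    for cls, labels in summary.frame_pct.items():
        total = sum(labels.values())
        if labels and abs(total - 100.0) > 0.1:
            raise RetspliceError(f"frame percentages for {cls} sum to {total}")
    if summary.alignment is not None:
        a = summary.alignment
        if a.total_aligned != a.uniquely_aligned + a.non_uniquely_aligned:
            raise RetspliceError("alignment totals inconsistent")


def render_tables(summary: StudySummary) -> Dict[str, pd.DataFrame]:
    """TSV-ready tables of the summary (events, genes, alignment)."""
    events = pd.DataFrame([
        {"category": "novel_exons_total", "n": summary.n_novel_exons},
        {"category": "novel_exons_internal", "n": summary.n_internal_exons},
        {"category": "novel_exons_terminal", "n": summary.n_terminal_exons},
        {"category": "exon_skips", "n": summary.n_skips},
        {"category": "alt_sites_total", "n": summary.n_alt_sites},
        {"category": "alt3_sites", "n": summary.n_alt3},
        {"category": "alt5_sites", "n": summary.n_alt5},
        {"category": "total_novel_events", "n": summary.total_novel_events},
    ])
    out = {"events": events}
    if summary.alignment is not None:
        a = summary.alignment
        out["alignment"] = pd.DataFrame([
            {"category": "total_reads", "n": a.total_reads, "pct": ""},
            {"category": "uniquely_aligned", "n": a.uniquely_aligned,
             "pct": a.pct_unique},
            {"category": "non_uniquely_aligned", "n": a.non_uniquely_aligned,
             "pct": a.pct_non_unique},
            {"category": "total_aligned", "n": a.total_aligned,
             "pct": a.pct_aligned},
        ])
    if summary.n_novel_genes:
        out["genes"] = pd.DataFrame([
            {"category": "novel_genes", "n": summary.n_novel_genes},
            {"category": "protein_coding", "n": summary.n_coding_genes},
            {"category": "lincRNA_candidate", "n": summary.n_lincrna_genes},
        ])
    return out


def render_markdown(summary: StudySummary) -> str:
    lines = ["# Study summary", "",
             f"- Total novel splicing events: {summary.total_novel_events}",
             f"  - novel exons: {summary.n_novel_exons} "
             f"({summary.n_internal_exons} internal, "
             f"{summary.n_terminal_exons} terminal)",
             f"  - exon skipping: {summary.n_skips}",
             f"  - alternate splice sites: {summary.n_alt_sites} "
             f"({summary.n_alt3} alt3, {summary.n_alt5} alt5)"]
    if summary.n_reference_exons:
        lines.append(
            f"- Novel exons as % of reference exon catalog: "
            f"{summary.novel_exon_pct_of_reference:.1f}%")
    if summary.novel_junction_reads:
        lines.append(
            f"- Annotated:novel junction read fold: "
            f"{summary.annotated_novel_read_fold:.1f}x")
    if summary.n_novel_genes:
        lines.append(
            f"- Novel genes: {summary.n_novel_genes} "
            f"({summary.n_coding_genes} protein-coding, "
            f"{summary.n_lincrna_genes} lincRNA candidates)")
    if summary.added_bp or summary.removed_bp:
        lines.append(
            f"- Alt-site sequence change: +{summary.added_bp} bp added, "
            f"-{summary.removed_bp} bp removed")
    if summary.alignment is not None:
        a = summary.alignment
        lines += [
            "",
            "## Alignment",
            f"- total reads: {a.total_reads}",
            f"- uniquely aligned: {a.uniquely_aligned} ({a.pct_unique}%)",
            f"- total aligned: {a.total_aligned} ({a.pct_aligned}%)",
        ]
    return "\n".join(lines) + "\n"
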