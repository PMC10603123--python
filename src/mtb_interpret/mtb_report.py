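"""MTB report assembly and rendering.

A report opens with the clinical summary (passed through verbatim, never
synthesized), then one block per recommended therapy in rank order. Each
block lists the biomarkers of response and resistance, the supporting
evidence with its NCT level, matching biomarker-stratified trials, and a
free-text synthesis. A summary table repeats all therapies with level and
rank. Germline findings are filtered to ACMG classes 4 (likely pathogenic)
and 5 (pathogenic) — lower classes never appear in any rendered output.
Report generation is a pure function of its inputs: the same inputs render
to byte-identical JSON.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass
from typing import Any, Sequence

from mtb_interpret.core_io import QCResult
from mtb_interpret.evidence_engine import KnowledgeEntry, Recommendation
from mtb_interpret.scars import ScarMetrics


class ReportFormat(str, enum.Enum):
    JSON = "JSON"
    MARKDOWN = "MARKDOWN"


@dataclass(frozen=True)
class GermlineFinding:
    gene: str
    hgvs: str
    acmg_class: int
    counseling_recommended: bool = False

    def __post_init__(self) -> None:
        if self.acmg_class not in (1, 2, 3, 4, 5):
            raise ValueError(f"ACMG class must be 1-5, got {self.acmg_class}")


def filter_germline(findings: Sequence[GermlineFinding]) -> list[GermlineFinding]:
    """Keep only reportable germline findings (ACMG class 4 or 5)."""
    return [f for f in findings if f.acmg_class >= 4]


@dataclass
class ReportBlock:
    """One therapy recommendation block."""

    therapy_name: str
    response_biomarkers: list[str]
    resistance_biomarkers: list[str]
    evidence_text: str
    level: str
    level_range: str | None
    trials: list[str]
    summary: str
    basket: str
    rank: int


@dataclass
class MTBReport:
    sample_id: str
    entity: str
    clinical_summary: str
    blocks: list[ReportBlock]
    summary_table: list[dict[str, Any]]
    germline: list[GermlineFinding]
    qc: QCResult | None
    scar_metrics: ScarMetrics | None
    provenance: dict[str, Any]


def _config_hash(config: dict[str, Any]) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(
    sample_id: str,
    entity: str,
    clinical_summary: str,
    recommendations: Sequence[Recommendation],
    germline: Sequence[GermlineFinding] = (),
    resistance_entries: Sequence[KnowledgeEntry] = (),
    qc: QCResult | None = None,
    scar_metrics: ScarMetrics | None = None,
    config: dict[str, Any] | None = None,
    seed: int | None = None,
    block_summaries: dict[str, str] | None = None,
) -> MTBReport:
    """Assemble the structured MTB report.

    Recommendations must already be ranked; blocks appear in rank order,
    each ordered internally as biomarkers, evidence with level, trials,
    summary. Germline findings are filtered to ACMG 4/5 here, so no
    lower-class finding can reach a renderer. An empty recommendation list
    yields an explicit "no molecularly informed option" block.
    """
    config = config or {}
    block_summaries = block_summaries or {}
    if any(r.rank is None for r in recommendations):
        raise ValueError("recommendations must be ranked before report assembly")
    ranked = sorted(recommendations, key=lambda r: r.rank)

    resistance_by_gene = [
        f"{e.gene} ({e.drug})" for e in resistance_entries
    ]
    blocks: list[ReportBlock] = []
    for rec in ranked:
        level_range = (
            f"{rec.level_range[0]}-{rec.level_range[1]}" if rec.level_range else None
        )
        evidence_bits = [f"NCT evidence level {rec.level}"]
        if rec.references:
            evidence_bits.append("references: " + "; ".join(rec.references))
        blocks.append(
            ReportBlock(
                therapy_name=rec.drug,
                response_biomarkers=[
                    f"{b.gene_or_name} ({b.kind.value}, {b.source_layer.value})"
                    + (f": {b.detail}" if b.detail else "")
                    for b in rec.biomarkers
                ],
                resistance_biomarkers=resistance_by_gene,
                evidence_text="; ".join(evidence_bits),
                level=str(rec.level),
                level_range=level_range,
                trials=[rec.trial_id] if rec.trial_id else [],
                summary=block_summaries.get(rec.drug, ""),
                basket=rec.basket.value,
                rank=rec.rank,
            )
        )
    summary_table = [
        {"therapy": b.therapy_name, "level": b.level, "rank": b.rank}
        for b in blocks
    ]
    if not blocks:
        summary_table = []
    provenance = {
        "package": "mtb-interpret",
        "config_hash": _config_hash(config),
        "seed": seed,
    }
    return MTBReport(
        sample_id=sample_id,
        entity=entity,
        clinical_summary=clinical_summary,
        blocks=blocks,
        summary_table=summary_table,
        germline=filter_germline(germline),
        qc=qc,
        scar_metrics=scar_metrics,
        provenance=provenance,
    )


NO_OPTION_TEXT = "No molecularly informed treatment option could be recommended."


def _report_dict(report: MTBReport) -> dict[str, Any]:
    d: dict[str, Any] = {
        "sample_id": report.sample_id,
        "entity": report.entity,
        "clinical_summary": report.clinical_summary,
        "blocks": [
            {
                "therapy": b.therapy_name,
                "response_biomarkers": b.response_biomarkers,
                "resistance_biomarkers": b.resistance_biomarkers,
                "evidence": b.evidence_text,
                "level": b.level,
                "level_range": b.level_range,
                "trials": b.trials,
                "summary": b.summary,
                "basket": b.basket,
                "rank": b.rank,
            }
            for b in report.blocks
        ],
        "summary_table": report.summary_table,
        "germline_findings": [
            {
                "gene": g.gene,
                "hgvs": g.hgvs,
                "acmg_class": g.acmg_class,
                "counseling_recommended": g.counseling_recommended,
            }
            for g in report.germline
        ],
        "provenance": report.provenance,
    }
    if not report.blocks:
        d["no_option"] = NO_OPTION_TEXT
    if report.qc is not None:
        d["qc"] = {
            "passed": report.qc.passed,
            "failures": [
                {"check": f.check, "observed": f.observed, "threshold": f.threshold}
                for f in report.qc.failures
            ],
        }
    if report.scar_metrics is not None:
        sm = report.scar_metrics
        d["scar_metrics"] = {
            "hrd_loh": sm.hrd_loh,
            "lst": sm.lst,
            "ploidy": round(sm.ploidy, 4),
            "segment_count": sm.segment_count,
        }
    return d


def render(report: MTBReport, format: ReportFormat = ReportFormat.JSON) -> str:
    """Render the report as canonical JSON or Markdown.

    JSON is emitted with sorted keys and fixed separators, so equal reports
    render byte-identically; Markdown has one section per block plus the
    summary table.
    """
    format = ReportFormat(format)
    if format is ReportFormat.JSON:
        return json.dumps(_report_dict(report), sort_keys=True, indent=2)
    if format is ReportFormat.MARKDOWN:
        return _render_markdown(report)
    raise ValueError(f"unknown report format {format!r}")


def _render_markdown(report: MTBReport) -> str:
    lines: list[str] = [
        f"# MTB report — {report.sample_id}",
        "",
        f"**Entity:** {report.entity}",
        "",
        "## Clinical summary",
        "",
        report.clinical_summary or "(not provided)",
        "",
    ]
    if report.scar_metrics is not None:
        sm = report.scar_metrics
        lines += [
            "## Genomic scar metrics",
            "",
            f"- HRD-LOH score: {sm.hrd_loh}",
            f"- LST count: {sm.lst}",
            f"- Average ploidy: {sm.ploidy:.2f}",
            "",
        ]
    lines += ["## Therapy recommendations", ""]
    if not report.blocks:
        lines += [NO_OPTION_TEXT, ""]
    for b in report.blocks:
        lines += [f"### {b.rank}. {b.therapy_name}", ""]
        lines += ["**Biomarkers of response:**"]
        lines += [f"- {m}" for m in b.response_biomarkers] or ["- (none)"]
        if b.resistance_biomarkers:
            lines += ["", "**Biomarkers of resistance:**"]
            lines += [f"- {m}" for m in b.resistance_biomarkers]
        level_text = b.level_range or b.level
        lines += ["", f"**Evidence:** {b.evidence_text} (level {level_text})"]
        if b.trials:
            lines += ["", "**Trials:** " + ", ".join(b.trials)]
        if b.summary:
            lines += ["", f"**Summary:** {b.summary}"]
        lines += [""]
    lines += ["## Summary of recommendations", ""]
    lines += ["| Rank | Therapy | Evidence level |", "|---|---|---|"]
    for row in report.summary_table:
        lines += [f"| {row['rank']} | {row['therapy']} | {row['level']} |"]
    lines += [""]
    if report.germline:
        lines += ["## Germline findings (ACMG class 4/5)", ""]
        for g in report.germline:
            counsel = "; genetic counseling recommended" if g.counseling_recommended else ""
            lines += [f"- {g.gene} {g.hgvs} (ACMG class {g.acmg_class}{counsel})"]
        lines += [""]
    return "\n".join(lines)
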