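"""End-to-end: biomarkers -> evidence levels -> ranked recommendations -> report.

A KIT-mutant case with an HRD scar signature: observations are matched
against a small knowledge table, NCT evidence levels assigned (m1 same
entity, m2 other entity, m3 preclinical, m4 rationale; suffixes a/b/c by
study type), recommendations ranked (trials before off-label at equal
level), germline findings filtered to ACMG class 4/5, and the report
rendered as Markdown.
"""

from mtb_interpret.evidence_engine import (
    BiomarkerKind,
    BiomarkerObservation,
    KnowledgeEntry,
    SourceLayer,
    StudyType,
    match_observations,
    rank_recommendations,
)
from mtb_interpret.mtb_report import (
    GermlineFinding,
    ReportFormat,
    build_report,
    render,
)

observations = [
    BiomarkerObservation(BiomarkerKind.SMALL_VARIANT, "KIT",
                         detail="exon 11 in-frame insertion",
                         source_layer=SourceLayer.BOTH),
    BiomarkerObservation(BiomarkerKind.SCAR_HRD, "HRD",
                         detail="HRD-LOH 19, LST 23"),
]
knowledge = [
    KnowledgeEntry(BiomarkerKind.SMALL_VARIANT, "KIT", "GIST", "imatinib",
                   drug_class="TKI", study_type=StudyType.PROSPECTIVE_OR_META,
                   references=("PMID:18235122",)),
    KnowledgeEntry(BiomarkerKind.SCAR_HRD, "*", "*", "olaparib",
                   drug_class="PARPi", study_type=StudyType.RETROSPECTIVE,
                   trial_id="NCT-EXAMPLE-01"),
]
recs, resistance = match_observations(observations, knowledge, "GIST")
ranked = rank_recommendations(recs)

germline = [
    GermlineFinding("CHEK2", "p.I157T", acmg_class=3),
    GermlineFinding("BRCA2", "p.S1982fs", acmg_class=5, counseling_recommended=True),
]
report = build_report(
    sample_id="EXAMPLE-1",
    entity="GIST",
    clinical_summary="Progressive disease on first-line therapy.",
    recommendations=ranked,
    germline=germline,
    block_summaries={"imatinib": "Exon 11 KIT mutations predict deep responses."},
)
print(render(report, ReportFormat.MARKDOWN))
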