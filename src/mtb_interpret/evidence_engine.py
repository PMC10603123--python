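"""Biomarker-drug matching, NCT evidence levels, baskets, and ranking.

NCT evidence levels grade the support behind a biomarker-drug association:
m1 for clinical evidence in the patient's own entity, m2 for clinical
evidence in a different entity, m3 for preclinical evidence, m4 for a
biological rationale. Levels m1 and m2 carry a suffix for the study type —
a: prospective study or meta-analysis; b: retrospective cohort or
case-control study; c: case study or single unusual responder. Actionable
alterations are organised into seven biomarker baskets by pathway/process.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class BiomarkerKind(str, enum.Enum):
    SMALL_VARIANT = "SMALL_VARIANT"
    AMPLIFICATION = "AMPLIFICATION"
    DELETION_BIALLELIC = "DELETION_BIALLELIC"
    FUSION = "FUSION"
    OVEREXPRESSION = "OVEREXPRESSION"
    SCAR_HRD = "SCAR_HRD"
    TMB_HIGH = "TMB_HIGH"
    SIGNATURE = "SIGNATURE"


class SourceLayer(str, enum.Enum):
    DNA = "DNA"
    RNA = "RNA"
    BOTH = "BOTH"


class StudyType(str, enum.Enum):
    PROSPECTIVE_OR_META = "PROSPECTIVE_OR_META"
    RETROSPECTIVE = "RETROSPECTIVE"
    CASE = "CASE"
    PRECLINICAL = "PRECLINICAL"
    RATIONALE = "RATIONALE"


class Basket(str, enum.Enum):
    TYROSINE_KINASES = "tyrosine kinases"
    PI3K_AKT_MTOR = "PI3K-AKT-mTOR signaling"
    RAF_MEK_ERK = "RAF-MEK-ERK signaling"
    CELL_CYCLE = "cell cycle"
    DEVELOPMENTAL_REGULATION = "developmental regulation"
    DNA_DAMAGE_REPAIR = "DNA damage repair"
    IMMUNE_EVASION = "immune evasion"
    UNASSIGNED = "unassigned"


class Polarity(str, enum.Enum):
    RESPONSE = "RESPONSE"
    RESISTANCE = "RESISTANCE"


@dataclass(frozen=True)
class BiomarkerObservation:
    """One observed biomarker, from whichever omics layer detected it."""

    kind: BiomarkerKind
    gene_or_name: str
    detail: str = ""
    source_layer: SourceLayer = SourceLayer.DNA
    whitelisted: bool = False


@dataclass(frozen=True)
class KnowledgeEntry:
    """One entity-biomarker-drug association from the knowledge table."""

    kind: BiomarkerKind
    gene: str
    entity: str  # histology label or "*" for any entity
    drug: str
    drug_class: str = ""
    study_type: StudyType = StudyType.RATIONALE
    trial_id: str | None = None
    references: tuple[str, ...] = ()
    polarity: Polarity = Polarity.RESPONSE
    detail_matcher: str = ""

    def matches(self, obs: BiomarkerObservation) -> bool:
        if self.kind is not obs.kind:
            return False
        if self.gene != "*" and self.gene.upper() != obs.gene_or_name.upper():
            return False
        if self.detail_matcher and self.detail_matcher.lower() not in obs.detail.lower():
            return False
        return True


class Tier(str, enum.Enum):
    m1 = "m1"
    m2 = "m2"
    m3 = "m3"
    m4 = "m4"


class Suffix(str, enum.Enum):
    a = "a"
    b = "b"
    c = "c"
    none = ""


_SUFFIX_FOR_STUDY = {
    StudyType.PROSPECTIVE_OR_META: Suffix.a,
    StudyType.RETROSPECTIVE: Suffix.b,
    StudyType.CASE: Suffix.c,
}


@dataclass(frozen=True)
class EvidenceLevel:
    tier: Tier
    suffix: Suffix = Suffix.none

    def __post_init__(self) -> None:
        clinical = self.tier in (Tier.m1, Tier.m2)
        if clinical and self.suffix is Suffix.none:
            raise ValueError(f"{self.tier.value} requires a study-type suffix")
        if not clinical and self.suffix is not Suffix.none:
            raise ValueError(f"{self.tier.value} takes no suffix")

    def __str__(self) -> str:
        return f"{self.tier.value}{self.suffix.value}"

    @property
    def sort_key(self) -> tuple[int, int]:
        tiers = [Tier.m1, Tier.m2, Tier.m3, Tier.m4]
        suffixes = [Suffix.a, Suffix.b, Suffix.c, Suffix.none]
        return (tiers.index(self.tier), suffixes.index(self.suffix))

    @classmethod
    def parse(cls, text: str) -> "EvidenceLevel":
        tier = Tier(text[:2])
        suffix = Suffix(text[2:]) if len(text) > 2 else Suffix.none
        return cls(tier, suffix)


ALL_LEVELS: tuple[EvidenceLevel, ...] = tuple(
    EvidenceLevel.parse(t) for t in ("m1a", "m1b", "m1c", "m2a", "m2b", "m2c", "m3", "m4")
)


def normalize_entity(entity: str) -> str:
    return " ".join(entity.strip().lower().split())


def assign_level(
    entry: KnowledgeEntry,
    patient_entity: str,
    aliases: Mapping[str, str] | None = None,
) -> EvidenceLevel:
    """NCT evidence level for a knowledge entry applied to a patient.

    Preclinical evidence gives m3 and a biological rationale m4 regardless
    of entity. Clinical evidence gives m1 when the entry's entity matches
    the patient's histology (exact match after normalization, optionally
    through an alias table; "*" matches any entity), otherwise m2; the
    suffix encodes the study type (a/b/c).
    """
    if entry.study_type is StudyType.PRECLINICAL:
        return EvidenceLevel(Tier.m3)
    if entry.study_type is StudyType.RATIONALE:
        return EvidenceLevel(Tier.m4)
    suffix = _SUFFIX_FOR_STUDY[entry.study_type]
    patient = normalize_entity(patient_entity)
    entry_entity = normalize_entity(entry.entity)
    if aliases:
        norm_aliases = {normalize_entity(k): normalize_entity(v) for k, v in aliases.items()}
        patient = norm_aliases.get(patient, patient)
        entry_entity = norm_aliases.get(entry_entity, entry_entity)
    same_entity = entry.entity == "*" or entry_entity == patient
    return EvidenceLevel(Tier.m1 if same_entity else Tier.m2, suffix)


def level_order(levels: Iterable[EvidenceLevel]) -> list[EvidenceLevel]:
    """Sort levels strongest first: m1a < m1b < m1c < m2a < m2b < m2c < m3 < m4.

    Stable for ties and idempotent.
    """
    return sorted(levels, key=lambda lv: lv.sort_key)


#: curated default gene -> basket map (extend or replace via TSV)
DEFAULT_BASKET_MAP: dict[str, Basket] = {
    "KIT": Basket.TYROSINE_KINASES,
    "PDGFRA": Basket.TYROSINE_KINASES,
    "PDGFRB": Basket.TYROSINE_KINASES,
    "EGFR": Basket.TYROSINE_KINASES,
    "ERBB2": Basket.TYROSINE_KINASES,
    "ALK": Basket.TYROSINE_KINASES,
    "ROS1": Basket.TYROSINE_KINASES,
    "RET": Basket.TYROSINE_KINASES,
    "MET": Basket.TYROSINE_KINASES,
    "NTRK1": Basket.TYROSINE_KINASES,
    "NTRK2": Basket.TYROSINE_KINASES,
    "NTRK3": Basket.TYROSINE_KINASES,
    "FGFR1": Basket.TYROSINE_KINASES,
    "FGFR2": Basket.TYROSINE_KINASES,
    "FGFR3": Basket.TYROSINE_KINASES,
    "PIK3CA": Basket.PI3K_AKT_MTOR,
    "PTEN": Basket.PI3K_AKT_MTOR,
    "AKT1": Basket.PI3K_AKT_MTOR,
    "MTOR": Basket.PI3K_AKT_MTOR,
    "TSC1": Basket.PI3K_AKT_MTOR,
    "TSC2": Basket.PI3K_AKT_MTOR,
    "STK11": Basket.PI3K_AKT_MTOR,
    "BRAF": Basket.RAF_MEK_ERK,
    "NRAS": Basket.RAF_MEK_ERK,
    "KRAS": Basket.RAF_MEK_ERK,
    "HRAS": Basket.RAF_MEK_ERK,
    "MAP2K1": Basket.RAF_MEK_ERK,
    "NF1": Basket.RAF_MEK_ERK,
    "CDK4": Basket.CELL_CYCLE,
    "CDK6": Basket.CELL_CYCLE,
    "CCND1": Basket.CELL_CYCLE,
    "CDKN2A": Basket.CELL_CYCLE,
    "CDKN2B": Basket.CELL_CYCLE,
    "RB1": Basket.CELL_CYCLE,
    "MDM2": Basket.CELL_CYCLE,
    "TP53": Basket.CELL_CYCLE,
    "PLAG1": Basket.DEVELOPMENTAL_REGULATION,
    "NOTCH1": Basket.DEVELOPMENTAL_REGULATION,
    "SMO": Basket.DEVELOPMENTAL_REGULATION,
    "PTCH1": Basket.DEVELOPMENTAL_REGULATION,
    "CTNNB1": Basket.DEVELOPMENTAL_REGULATION,
    "BRCA1": Basket.DNA_DAMAGE_REPAIR,
    "BRCA2": Basket.DNA_DAMAGE_REPAIR,
    "ATM": Basket.DNA_DAMAGE_REPAIR,
    "ATR": Basket.DNA_DAMAGE_REPAIR,
    "PALB2": Basket.DNA_DAMAGE_REPAIR,
    "CHEK2": Basket.DNA_DAMAGE_REPAIR,
    "RAD51B": Basket.DNA_DAMAGE_REPAIR,
    "MLH1": Basket.DNA_DAMAGE_REPAIR,
    "MSH2": Basket.DNA_DAMAGE_REPAIR,
    "CD274": Basket.IMMUNE_EVASION,
    "PDCD1": Basket.IMMUNE_EVASION,
    "B2M": Basket.IMMUNE_EVASION,
    "TACSTD2": Basket.UNASSIGNED,  # ADC target; surface antigen, not a pathway
}

#: signature names treated as HRD-associated for basket assignment
HRD_SIGNATURES = frozenset({"SBS3"})


def assign_basket(
    observation: BiomarkerObservation,
    basket_map: Mapping[str, Basket] | None = None,
) -> Basket:
    """Assign a biomarker to one of the seven baskets.

    HRD scars and HRD-associated signatures (SBS3-like) go to DNA damage
    repair; high TMB to immune evasion; genes via the curated map; unmapped
    genes to "unassigned".
    """
    bmap = dict(DEFAULT_BASKET_MAP)
    if basket_map:
        bmap.update(basket_map)
    if observation.kind is BiomarkerKind.SCAR_HRD:
        return Basket.DNA_DAMAGE_REPAIR
    if observation.kind is BiomarkerKind.SIGNATURE:
        name = observation.gene_or_name.upper()
        if name in HRD_SIGNATURES or "HRD" in observation.detail.upper():
            return Basket.DNA_DAMAGE_REPAIR
        return Basket.UNASSIGNED
    if observation.kind is BiomarkerKind.TMB_HIGH:
        return Basket.IMMUNE_EVASION
    return bmap.get(observation.gene_or_name.upper(), Basket.UNASSIGNED)


@dataclass
class Recommendation:
    """One drug or trial option with its evidence and ranking inputs."""

    drug: str
    biomarkers: tuple[BiomarkerObservation, ...]
    level: EvidenceLevel
    basket: Basket
    is_trial: bool = False
    trial_id: str | None = None
    level_range: tuple[EvidenceLevel, EvidenceLevel] | None = None  # (best, worst)
    drug_class: str = ""
    references: tuple[str, ...] = ()
    rank: int | None = None

    @property
    def dual_layer(self) -> bool:
        layers = {b.source_layer for b in self.biomarkers}
        return SourceLayer.BOTH in layers or {SourceLayer.DNA, SourceLayer.RNA} <= layers

    @property
    def ranking_level(self) -> EvidenceLevel:
        """Scalar level used for ranking: the best end of a range."""
        return self.level_range[0] if self.level_range else self.level


def match_observations(
    observations: Sequence[BiomarkerObservation],
    knowledge: Sequence[KnowledgeEntry],
    patient_entity: str,
    aliases: Mapping[str, str] | None = None,
    basket_map: Mapping[str, Basket] | None = None,
) -> tuple[list[Recommendation], list[KnowledgeEntry]]:
    """Match observed biomarkers against the knowledge table.

    Response-polarity matches become candidate recommendations (one per
    drug, pooling all supporting biomarkers at the best evidence level);
    resistance-polarity matches are returned separately for rendering —
    they are never ranked as therapies.
    """
    per_drug: dict[str, Recommendation] = {}
    resistance: list[KnowledgeEntry] = []
    for entry in knowledge:
        matched = [obs for obs in observations if entry.matches(obs)]
        if not matched:
            continue
        if entry.polarity is Polarity.RESISTANCE:
            resistance.append(entry)
            continue
        level = assign_level(entry, patient_entity, aliases)
        existing = per_drug.get(entry.drug)
        if existing is None:
            per_drug[entry.drug] = Recommendation(
                drug=entry.drug,
                biomarkers=tuple(matched),
                level=level,
                basket=assign_basket(matched[0], basket_map),
                is_trial=entry.trial_id is not None,
                trial_id=entry.trial_id,
                drug_class=entry.drug_class,
                references=entry.references,
            )
        else:
            pooled = tuple(dict.fromkeys(existing.biomarkers + tuple(matched)))
            best = level_order([existing.level, level])[0]
            worst = level_order([existing.level, level])[-1]
            existing.biomarkers = pooled
            existing.level = best
            if best != worst:
                existing.level_range = (best, worst)
            if entry.trial_id and not existing.trial_id:
                existing.is_trial = True
                existing.trial_id = entry.trial_id
            existing.references = tuple(dict.fromkeys(existing.references + entry.references))
    return list(per_drug.values()), resistance


def rank_recommendations(
    recs: Sequence[Recommendation], prefer_trials: bool = True
) -> list[Recommendation]:
    """Rank recommendations strongest first and assign ranks 1..n.

    Primary key is the evidence level; trials come before off-label options
    at the same level (so an off-label therapy with a *higher* level still
    outranks a trial); biomarkers supported by both DNA and RNA break
    remaining ties; input order is preserved for exact ties (stable sort).
    """
    def key(item: tuple[int, Recommendation]):
        i, rec = item
        trial_key = (0 if rec.is_trial else 1) if prefer_trials else 0
        return (rec.ranking_level.sort_key, trial_key, 0 if rec.dual_layer else 1, i)

    ordered = [rec for _, rec in sorted(enumerate(recs), key=key)]
    for i, rec in enumerate(ordered, start=1):
        rec.rank = i
    return ordered


# ---------------------------------------------------------------------------
# Knowledge table I/O
# ---------------------------------------------------------------------------


def read_knowledge_table(path: str | Path) -> list[KnowledgeEntry]:
    """Read a knowledge TSV with columns kind, gene, entity, drug,
    drug_class, study_type, trial_id, references, polarity, detail."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in header}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")

            def get(col: str, default: str = "") -> str:
                return f[idx[col]] if col in idx and len(f) > idx[col] else default

            refs = tuple(r for r in get("references").split(";") if r)
            entries.append(
                KnowledgeEntry(
                    kind=BiomarkerKind(get("kind")),
                    gene=get("gene"),
                    entity=get("entity", "*"),
                    drug=get("drug"),
                    drug_class=get("drug_class"),
                    study_type=StudyType(get("study_type", "RATIONALE")),
                    trial_id=get("trial_id") or None,
                    references=refs,
                    polarity=Polarity(get("polarity", "RESPONSE")),
                    detail_matcher=get("detail"),
                )
            )
    return entries
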