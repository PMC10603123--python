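"""Somatic small variants: VCF intake, TMB, VICC oncogenicity scoring, and
the control-sample mosaicism flag.

The VICC engine consumes *asserted* criteria (curator judgements with notes);
automated criterion evaluation against hotspot or population databases is a
curation step upstream of this package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

from mtb_interpret.core_io import GenomicInterval, normalize_chrom


class VariantType(str, enum.Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    DELINS = "DELINS"


@dataclass
class SmallVariant:
    """One somatic SNV/indel (one record per ALT allele)."""

    gene: str
    hgvs_p: str
    interval: GenomicInterval
    ref: str
    alt: str
    variant_type: VariantType
    consequence: str
    dna_af: float
    rna_af: float | None = None
    control_af: float | None = None
    expressed: bool | None = None

    def __post_init__(self) -> None:
        for name, af in (
            ("dna_af", self.dna_af),
            ("rna_af", self.rna_af),
            ("control_af", self.control_af),
        ):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {af}")

    @property
    def key(self) -> str:
        return f"{self.interval.chrom}:{self.interval.start}:{self.ref}>{self.alt}"


def classify_alleles(ref: str, alt: str) -> VariantType:
    if len(ref) == 1 and len(alt) == 1:
        return VariantType.SNV
    if len(ref) < len(alt) and alt.startswith(ref):
        return VariantType.INS
    if len(ref) > len(alt) and ref.startswith(alt):
        return VariantType.DEL
    return VariantType.DELINS


def _sample_af(sample) -> float | None:
    """Allele fraction from FORMAT/AF, falling back to AD."""
    af = sample.get("AF")
    if af is not None:
        return float(af[0] if isinstance(af, tuple) else af)
    ad = sample.get("AD")
    if ad is not None and len(ad) >= 2 and ad[0] is not None:
        depth = sum(x for x in ad if x is not None)
        if depth > 0:
            return ad[1] / depth
    return None


def read_vcf(
    path: str | Path,
    tumor_sample: str | None = None,
    control_sample: str | None = None,
) -> list[SmallVariant]:
    """Read somatic small variants from a VCF (v4.x).

    One SmallVariant is emitted per ALT allele. The tumor allele fraction is
    taken from FORMAT/AF, or computed from FORMAT/AD when AF is absent. Gene
    and consequence come from the INFO fields GENE and CSQ when present
    (else "unknown"). With a matched control sample, its allele fraction is
    stored as control_af for mosaicism assessment.
    """
    variants: list[SmallVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ValueError(f"{path}: VCF has no sample columns")
        tumor = tumor_sample or samples[0]
        if tumor not in samples:
            raise ValueError(f"{path}: tumor sample {tumor!r} not in VCF")
        control = control_sample
        if control is None and len(samples) > 1:
            control = samples[1]
        for rec in vcf:
            if not rec.alts:
                continue
            gene = str(_info_get(rec, "GENE", "unknown"))
            consequence = str(_info_get(rec, "CSQ", "unknown"))
            hgvs_p = str(_info_get(rec, "HGVSP", ""))
            for alt_i, alt in enumerate(rec.alts):
                tumor_af = _per_allele_af(rec.samples[tumor], alt_i)
                if tumor_af is None:
                    continue
                control_af = (
                    _per_allele_af(rec.samples[control], alt_i)
                    if control is not None
                    else None
                )
                ref = rec.ref
                end = rec.pos + len(ref) - 1
                variants.append(
                    SmallVariant(
                        gene=gene,
                        hgvs_p=hgvs_p,
                        interval=GenomicInterval(normalize_chrom(rec.chrom), rec.pos, end),
                        ref=ref,
                        alt=alt,
                        variant_type=classify_alleles(ref, alt),
                        consequence=consequence,
                        dna_af=min(max(tumor_af, 0.0), 1.0),
                        control_af=control_af,
                    )
                )
    return variants


def _info_get(rec, key: str, default):
    # pysam raises for INFO keys absent from the header
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _per_allele_af(sample, alt_index: int) -> float | None:
    af = sample.get("AF")
    if af is not None:
        if isinstance(af, tuple):
            return float(af[alt_index]) if alt_index < len(af) else None
        return float(af)
    ad = sample.get("AD")
    if ad is not None and len(ad) >= alt_index + 2:
        depth = sum(x for x in ad if x is not None)
        allele = ad[alt_index + 1]
        if depth and allele is not None:
            return allele / depth
    return None


# ---------------------------------------------------------------------------
# VICC point-based oncogenicity scoring
# ---------------------------------------------------------------------------

#: oncogenic evidence criteria and their benign counterparts
VICC_CODES = (
    "OVS1",
    "OS1", "OS2", "OS3",
    "OM1", "OM2", "OM3", "OM4",
    "OP1", "OP2", "OP3", "OP4",
    "SBVS1",
    "SBS1", "SBS2",
    "SBP1", "SBP2",
)

#: very strong 8, strong 4, moderate 2, supporting 1; benign mirrored negative
DEFAULT_VICC_WEIGHTS: dict[str, int] = {
    "OVS1": 8,
    **{c: 4 for c in ("OS1", "OS2", "OS3")},
    **{c: 2 for c in ("OM1", "OM2", "OM3", "OM4")},
    **{c: 1 for c in ("OP1", "OP2", "OP3", "OP4")},
    "SBVS1": -8,
    "SBS1": -4,
    "SBS2": -4,
    "SBP1": -1,
    "SBP2": -1,
}


class Oncogenicity(str, enum.Enum):
    ONCOGENIC = "ONCOGENIC"
    LIKELY_ONCOGENIC = "LIKELY_ONCOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


#: classification bands as (inclusive lower bound, class), strongest first
DEFAULT_CLASS_BANDS: tuple[tuple[int, Oncogenicity], ...] = (
    (10, Oncogenicity.ONCOGENIC),
    (6, Oncogenicity.LIKELY_ONCOGENIC),
    (0, Oncogenicity.VUS),
    (-6, Oncogenicity.LIKELY_BENIGN),
)


@dataclass(frozen=True)
class CriterionEvidence:
    """One asserted VICC criterion with the curator's note."""

    code: str
    met: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.code not in VICC_CODES:
            raise ValueError(f"unknown VICC criterion code {self.code!r}")


@dataclass(frozen=True)
class OncogenicityResult:
    score: int
    classification: Oncogenicity
    criteria_applied: tuple[CriterionEvidence, ...]


def classify_score(
    score: int,
    bands: Sequence[tuple[int, Oncogenicity]] = DEFAULT_CLASS_BANDS,
) -> Oncogenicity:
    for lower, cls in bands:
        if score >= lower:
            return cls
    return Oncogenicity.BENIGN


def vicc_score(
    criteria: Iterable[CriterionEvidence],
    weights: Mapping[str, int] | None = None,
    bands: Sequence[tuple[int, Oncogenicity]] = DEFAULT_CLASS_BANDS,
) -> OncogenicityResult:
    """Aggregate asserted VICC criteria into a point score and class.

    Score = sum of weights of met criteria (very strong 8, strong 4,
    moderate 2, supporting 1; benign evidence mirrored negative). Default
    bands: >= 10 oncogenic, 6-9 likely oncogenic, 0-5 VUS, -6..-1 likely
    benign, <= -7 benign.
    """
    weights = dict(weights) if weights is not None else DEFAULT_VICC_WEIGHTS
    criteria = tuple(criteria)
    seen: set[str] = set()
    score = 0
    for ev in criteria:
        if ev.code not in weights:
            raise ValueError(f"criterion {ev.code!r} has no weight")
        if ev.code in seen:
            raise ValueError(f"duplicate criterion code {ev.code!r}")
        seen.add(ev.code)
        if ev.met:
            score += weights[ev.code]
    return OncogenicityResult(
        score=score,
        classification=classify_score(score, bands),
        criteria_applied=criteria,
    )


# ---------------------------------------------------------------------------
# Tumor mutational burden
# ---------------------------------------------------------------------------

#: consequences that do not change the protein (excluded from default TMB)
SYNONYMOUS_CONSEQUENCES = frozenset(
    {"synonymous", "synonymous_variant", "intron", "intergenic", "utr", "upstream", "downstream"}
)


@dataclass(frozen=True)
class TMBResult:
    per_mbp: float
    snv_count: int
    indel_count: int
    qualifying: int
    footprint_mbp: float


def tmb(
    variants: Sequence[SmallVariant],
    coding_footprint_mbp: float = 38.0,
    nonsynonymous_only: bool = True,
) -> TMBResult:
    """Tumor mutational burden in mutations per coding megabase.

    Counts qualifying variants (non-synonymous by default) divided by the
    coding footprint; raw SNV and indel counts are reported alongside. The
    default 38 Mbp footprint approximates the protein-coding exome.
    """
    if coding_footprint_mbp <= 0:
        raise ValueError(f"coding footprint must be > 0, got {coding_footprint_mbp}")
    if nonsynonymous_only:
        qualifying = [
            v for v in variants if v.consequence not in SYNONYMOUS_CONSEQUENCES
        ]
    else:
        qualifying = list(variants)
    snvs = sum(1 for v in qualifying if v.variant_type is VariantType.SNV)
    indels = len(qualifying) - snvs
    return TMBResult(
        per_mbp=len(qualifying) / coding_footprint_mbp,
        snv_count=snvs,
        indel_count=indels,
        qualifying=len(qualifying),
        footprint_mbp=coding_footprint_mbp,
    )


# ---------------------------------------------------------------------------
# Control-sample mosaicism flag
# ---------------------------------------------------------------------------


class MosaicismFlag(str, enum.Enum):
    ABSENT = "ABSENT"
    POSSIBLE_MOSAIC = "POSSIBLE_MOSAIC"
    GERMLINE_HET_RANGE = "GERMLINE_HET_RANGE"


def mosaicism_flag(
    variant: SmallVariant, low: float = 0.02, high: float = 0.30
) -> MosaicismFlag:
    """Flag a somatic call whose allele fraction in the matched control
    suggests mosaicism.

    Control AF below ``low`` is treated as sequencing noise (ABSENT); in
    [low, high) as possible mosaicism warranting genetic counseling; at or
    above ``high`` as consistent with germline heterozygosity.
    """
    if variant.control_af is None:
        raise ValueError(
            f"variant {variant.key}: control_af missing, mosaicism not assessable"
        )
    af = variant.control_af
    if af < low:
        return MosaicismFlag.ABSENT
    if af < high:
        return MosaicismFlag.POSSIBLE_MOSAIC
    return MosaicismFlag.GERMLINE_HET_RANGE


def read_criteria_table(path: str | Path) -> dict[str, list[CriterionEvidence]]:
    """Read a sidecar TSV of asserted criteria (variant_key, code, met, note)."""
    out: dict[str, list[CriterionEvidence]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in header}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            key = f[idx["variant_key"]]
            met = f[idx["met"]].strip().lower() in ("1", "true", "yes")
            note = f[idx["note"]] if "note" in idx and len(f) > idx["note"] else ""
            out.setdefault(key, []).append(
                CriterionEvidence(code=f[idx["criterion"]], met=met, note=note)
            )
    return out
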