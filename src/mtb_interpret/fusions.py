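"""Gene-fusion functionality and actionability assessment.

A fusion joins a 5' partner (promoter and amino-terminal coding sequence)
to a 3' partner. Whether the chimera can be a drug target depends on three
questions answered here: is the junction in frame, does the chimeric
protein retain an intact kinase domain, and is the call supported by enough
reads. Oncogenicity alone does not make a fusion druggable — a promoter
swap that places an intact oncogene under the 5' partner's promoter is
oncogenic but offers no chimeric protein to inhibit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from mtb_interpret.core_io import GenomicInterval, normalize_chrom


@dataclass(frozen=True)
class ProteinDomain:
    name: str
    start_aa: int
    end_aa: int
    is_kinase: bool = False


@dataclass
class TranscriptModel:
    """One canonical transcript: exons in transcript (5'->3') order,
    genomic CDS boundaries, and protein domains in amino-acid coordinates."""

    gene: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int  # genomic position of first coding base
    cds_end: int  # genomic position of last coding base
    domains: tuple[ProteinDomain, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = tuple(self.exons)
        genomic_sorted = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic_sorted, genomic_sorted[1:]):
            if a.end >= b.start:
                raise ValueError(f"{self.gene}: overlapping exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.exons) != list(expected):
            raise ValueError(f"{self.gene}: exons must be ordered 5'->3' in transcript orientation")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )

    @property
    def tss(self) -> int:
        """Genomic position of the transcription start site."""
        return self.exons[0].start if self.strand == "+" else self.exons[0].end

    def _cds_lo_hi(self) -> tuple[int, int]:
        return min(self.cds_start, self.cds_end), max(self.cds_start, self.cds_end)

    @property
    def cds_length(self) -> int:
        lo, hi = self._cds_lo_hi()
        return sum(
            max(0, min(e.end, hi) - max(e.start, lo) + 1) for e in self.exons
        )

    def coding_bases_before(self, genomic_pos: int, inclusive: bool = True) -> int:
        """Coding bases transcript-upstream of ``genomic_pos``.

        With ``inclusive`` (the 5'-partner convention: the breakpoint is the
        last retained base) the base at ``genomic_pos`` is counted; without
        it (the 3'-partner convention: the breakpoint is the first retained
        base) counting stops just before the position.
        """
        lo, hi = self._cds_lo_hi()
        offset = 0 if inclusive else 1
        total = 0
        for exon in self.exons:
            c_lo, c_hi = max(exon.start, lo), min(exon.end, hi)
            if c_lo > c_hi:
                continue
            if self.strand == "+":
                pos = genomic_pos - offset
                if pos >= c_hi:
                    total += c_hi - c_lo + 1
                elif pos >= c_lo:
                    total += pos - c_lo + 1
            else:
                pos = genomic_pos + offset
                if pos <= c_lo:
                    total += c_hi - c_lo + 1
                elif pos <= c_hi:
                    total += c_hi - pos + 1
        return total

    def is_upstream_of_cds(self, genomic_pos: int) -> bool:
        """True iff ``genomic_pos`` lies transcript-upstream of both the
        transcription start and the start codon (i.e. in the promoter)."""
        if self.strand == "+":
            return genomic_pos < self.tss and genomic_pos < self.cds_start
        return genomic_pos > self.tss and genomic_pos > self.cds_start

    def within_span(self, genomic_pos: int) -> bool:
        return self.span.start <= genomic_pos <= self.span.end


@dataclass
class FusionEvent:
    """Two genomic breakpoints joined by a structural rearrangement,
    with the RNA read support for the junction."""

    gene5: str
    gene3: str
    chrom5: str
    breakpoint5: int
    chrom3: str
    breakpoint3: int
    split_reads: int = 0
    discordant_mates: int = 0

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.discordant_mates < 0:
            raise ValueError("read counts must be >= 0")

    @property
    def total_support(self) -> int:
        return self.split_reads + self.discordant_mates


class Frame(str, enum.Enum):
    IN_FRAME = "IN_FRAME"
    OUT_OF_FRAME = "OUT_OF_FRAME"
    PROMOTER_SWAP = "PROMOTER_SWAP"
    UNDETERMINED = "UNDETERMINED"


class FusionClass(str, enum.Enum):
    ACTIONABLE_KINASE_FUSION = "ACTIONABLE_KINASE_FUSION"
    ONCOGENIC_NOT_DRUGGABLE = "ONCOGENIC_NOT_DRUGGABLE"
    NON_FUNCTIONAL = "NON_FUNCTIONAL"
    LOW_SUPPORT = "LOW_SUPPORT"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class FrameResult:
    frame: Frame
    retained_cds5: int  # coding bases of the 5' gene retained
    excluded_cds3: int  # coding bases of the 3' gene lost upstream of its breakpoint
    reason: str = ""


@dataclass
class FusionAssessment:
    frame: Frame
    kinase_domain_retained: bool | None  # None = no kinase domain annotated
    support_pass: bool
    classification: FusionClass
    notes: list[str] = field(default_factory=list)


def assess_frame(
    event: FusionEvent, model5: TranscriptModel, model3: TranscriptModel
) -> FrameResult:
    """Determine the junction reading frame.

    Let L5 = coding bases of the 5' gene retained upstream of (and
    including) its breakpoint, and U3 = coding bases of the 3' gene excluded
    upstream of its breakpoint. The junction is IN_FRAME iff L5 > 0, the 3'
    gene retains coding sequence, and L5 == U3 (mod 3). If both breakpoints
    fall between promoter and transcription start — the 5' gene contributes
    no coding sequence and the 3' gene stays full length — the event is a
    PROMOTER_SWAP.
    """
    if not model5.within_span(event.breakpoint5) and not model5.is_upstream_of_cds(
        event.breakpoint5
    ):
        return FrameResult(Frame.UNDETERMINED, 0, 0, "5' breakpoint outside transcript span")
    if not model3.within_span(event.breakpoint3) and not model3.is_upstream_of_cds(
        event.breakpoint3
    ):
        return FrameResult(Frame.UNDETERMINED, 0, 0, "3' breakpoint outside transcript span")

    l5 = model5.coding_bases_before(event.breakpoint5, inclusive=True)
    u3 = model3.coding_bases_before(event.breakpoint3, inclusive=False)
    retained3 = model3.cds_length - u3

    if model5.is_upstream_of_cds(event.breakpoint5) and model3.is_upstream_of_cds(
        event.breakpoint3
    ):
        return FrameResult(
            Frame.PROMOTER_SWAP,
            0,
            0,
            "both breakpoints upstream of coding starts; 3' gene full length",
        )
    if l5 == 0 or retained3 <= 0:
        return FrameResult(
            Frame.UNDETERMINED, l5, u3, "no chimeric coding junction formed"
        )
    if l5 % 3 == u3 % 3:
        return FrameResult(Frame.IN_FRAME, l5, u3)
    return FrameResult(Frame.OUT_OF_FRAME, l5, u3)


def domain_retention(
    event: FusionEvent,
    kinase_model: TranscriptModel,
    frame_result: FrameResult | None = None,
) -> bool | None:
    """Is the kinase domain fully inside the retained coding portion?

    The kinase partner may be the 5' or the 3' gene; the domain's whole
    amino-acid interval must map within the retained coding sequence
    (boundary inclusive: a domain ending exactly at the last retained codon
    is retained). Returns None when no kinase domain is annotated.
    """
    kinase_domains = [d for d in kinase_model.domains if d.is_kinase]
    if not kinase_domains:
        return None
    if kinase_model.gene == event.gene5:
        retained_codons = (
            kinase_model.coding_bases_before(event.breakpoint5, inclusive=True) // 3
        )
        return any(d.end_aa <= retained_codons for d in kinase_domains)
    if kinase_model.gene == event.gene3:
        excluded = kinase_model.coding_bases_before(event.breakpoint3, inclusive=False)
        # first fully retained codon of the 3' partner
        first_codon = excluded // 3 + (1 if excluded % 3 == 0 else 2)
        return any(d.start_aa >= first_codon for d in kinase_domains)
    raise ValueError(f"{kinase_model.gene} is not a partner of this fusion")


def classify_fusion(
    frame: Frame,
    kinase_domain_retained: bool | None,
    split_reads: int,
    discordant_mates: int,
    min_reads: int = 2,
) -> FusionAssessment:
    """Decision table for fusion actionability.

    Support gate first (total reads >= min_reads, else LOW_SUPPORT); then:
    in-frame with retained kinase domain -> ACTIONABLE_KINASE_FUSION;
    out of frame -> NON_FUNCTIONAL; promoter swap, or in-frame without a
    kinase domain -> ONCOGENIC_NOT_DRUGGABLE; otherwise UNDETERMINED.
    """
    support_pass = (split_reads + discordant_mates) >= min_reads
    notes: list[str] = []
    if not support_pass:
        notes.append(f"read support below minimum of {min_reads}")
        cls = FusionClass.LOW_SUPPORT
    elif frame is Frame.IN_FRAME and kinase_domain_retained is True:
        cls = FusionClass.ACTIONABLE_KINASE_FUSION
    elif frame is Frame.OUT_OF_FRAME:
        cls = FusionClass.NON_FUNCTIONAL
        if kinase_domain_retained is False:
            notes.append("kinase domain only partially retained")
    elif frame is Frame.PROMOTER_SWAP or (
        frame is Frame.IN_FRAME and kinase_domain_retained in (None, False)
    ):
        cls = FusionClass.ONCOGENIC_NOT_DRUGGABLE
    else:
        cls = FusionClass.UNDETERMINED
    return FusionAssessment(
        frame=frame,
        kinase_domain_retained=kinase_domain_retained,
        support_pass=support_pass,
        classification=cls,
        notes=notes,
    )


def assess_fusion(
    event: FusionEvent,
    model5: TranscriptModel,
    model3: TranscriptModel,
    min_reads: int = 2,
) -> FusionAssessment:
    """Full pipeline for one fusion: frame, kinase retention, classification."""
    frame_result = assess_frame(event, model5, model3)
    kinase_model = None
    for model in (model5, model3):
        if any(d.is_kinase for d in model.domains):
            kinase_model = model
            break
    retained = (
        domain_retention(event, kinase_model, frame_result)
        if kinase_model is not None
        else None
    )
    assessment = classify_fusion(
        frame_result.frame,
        retained,
        event.split_reads,
        event.discordant_mates,
        min_reads=min_reads,
    )
    if frame_result.reason:
        assessment.notes.append(frame_result.reason)
    return assessment


# ---------------------------------------------------------------------------
# Arriba-style fusion TSV
# ---------------------------------------------------------------------------


def _parse_breakpoint(text: str) -> tuple[str, int]:
    chrom, pos = text.rsplit(":", 1)
    return normalize_chrom(chrom), int(pos)


def read_fusions(path: str | Path) -> list[FusionEvent]:
    """Read fusion calls from an Arriba-style TSV.

    Expected columns: gene1, gene2, breakpoint1, breakpoint2 (chrom:pos),
    split_reads1, split_reads2, discordant_mates. A leading '#' on the
    header (Arriba convention) is tolerated.
    """
    events = []
    with open(path) as fh:
        header = fh.readline().lstrip("#").rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in header}
        for col in ("gene1", "gene2", "breakpoint1", "breakpoint2"):
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            chrom5, bp5 = _parse_breakpoint(f[idx["breakpoint1"]])
            chrom3, bp3 = _parse_breakpoint(f[idx["breakpoint2"]])
            split = int(f[idx["split_reads1"]]) + int(f[idx["split_reads2"]]) if (
                "split_reads1" in idx and "split_reads2" in idx
            ) else 0
            disc = int(f[idx["discordant_mates"]]) if "discordant_mates" in idx else 0
            events.append(
                FusionEvent(
                    gene5=f[idx["gene1"]],
                    gene3=f[idx["gene2"]],
                    chrom5=chrom5,
                    breakpoint5=bp5,
                    chrom3=chrom3,
                    breakpoint3=bp3,
                    split_reads=split,
                    discordant_mates=disc,
                )
            )
    return events
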