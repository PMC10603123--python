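"""Allele-specific copy-number analytics: ploidy, LOH, genomic scar metrics
(HRD-LOH and LST), and ploidy-relative amplification / deletion calls with
second-hit logic.

Definitions
-----------
- Average ploidy: length-weighted mean total copy number over autosomal
  segments.
- LOH: minor copy-number state 0 with total state >= 1 (loss of one parental
  allele, retention of the other; homozygous deletions are excluded).
- HRD-LOH score: number of merged LOH runs longer than 15 Mbp that do not
  span an entire chromosome.
- LST count: number of switches between adjacent copy-number states where
  both flanking segments exceed 10 Mbp, counted per arm after smoothing away
  segments below 3 Mbp. High HRD-LOH and LST counts are genomic "scars" of
  homologous-recombination deficiency.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from mtb_interpret.core_io import (
    ArmDefinition,
    GenomicInterval,
    NotComputableError,
    arms_by_chrom,
)

MBP = 1_000_000

#: chromosomes excluded from average-ploidy computation
SEX_CHROMS = frozenset({"X", "Y"})


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number segment.

    total_cn and minor_cn are real-valued (purity-adjusted estimates);
    rounded integer states are available via ``total_state`` /
    ``minor_state``. minor_cn may be missing, in which case LOH-dependent
    metrics are not computable.
    """

    interval: GenomicInterval
    total_cn: float
    minor_cn: float | None = None

    def __post_init__(self) -> None:
        if self.total_cn < 0:
            raise ValueError(f"total_cn must be >= 0, got {self.total_cn}")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValueError(f"minor_cn must be >= 0, got {self.minor_cn}")
            if round(self.minor_cn) > round(self.total_cn) / 2:
                raise ValueError(
                    f"rounded minor state {round(self.minor_cn)} exceeds half of "
                    f"rounded total state {round(self.total_cn)}"
                )

    @property
    def total_state(self) -> int:
        return round(self.total_cn)

    @property
    def minor_state(self) -> int | None:
        return None if self.minor_cn is None else round(self.minor_cn)

    def state(self, allele_specific: bool = True) -> tuple:
        """Copy-number state used for LST switch comparison."""
        if allele_specific and self.minor_cn is not None:
            return (self.total_state, self.minor_state)
        return (self.total_state,)


@dataclass(frozen=True)
class ScarMetrics:
    hrd_loh: int
    lst: int
    ploidy: float
    segment_count: int


class CNACallType(str, enum.Enum):
    AMP = "AMP"
    GAIN = "GAIN"
    NEUTRAL = "NEUTRAL"
    HETLOSS = "HETLOSS"
    HOMDEL = "HOMDEL"


class SecondHit(str, enum.Enum):
    NONE = "NONE"
    MUTATION = "MUTATION"
    FOCAL_INTRAGENIC_DELETION = "FOCAL_INTRAGENIC_DELETION"
    LOH = "LOH"


@dataclass
class CNACall:
    """Ploidy-relative copy-number call for one gene."""

    gene: str
    total_cn: float
    ploidy: float
    call: CNACallType
    second_hit: SecondHit = SecondHit.NONE


def ploidy(segments: Sequence[CopyNumberSegment]) -> float:
    """Length-weighted mean total copy number over autosomal segments."""
    if not segments:
        raise ValueError("cannot compute ploidy of an empty segment list")
    autosomal = [s for s in segments if s.interval.chrom not in SEX_CHROMS]
    if not autosomal:
        raise ValueError("no autosomal segments")
    total_len = sum(s.interval.length for s in autosomal)
    weighted = sum(s.interval.length * s.total_cn for s in autosomal)
    return weighted / total_len


def detect_loh(segments: Sequence[CopyNumberSegment]) -> list[GenomicInterval]:
    """Merged maximal runs of loss of heterozygosity.

    A segment is LOH iff its rounded minor state is 0 and rounded total
    state >= 1 (homozygous deletions excluded: LOH means one parental allele
    is lost and the other retained). Abutting or adjacent-in-order LOH
    segments on the same chromosome merge into maximal runs.
    """
    for seg in segments:
        if seg.minor_cn is None:
            raise NotComputableError(
                f"minor_cn missing on {seg.interval.chrom}:{seg.interval.start}; "
                "LOH not computable"
            )
    loh = [
        s
        for s in sorted(segments, key=lambda s: (s.interval.chrom, s.interval.start))
        if s.minor_state == 0 and s.total_state >= 1
    ]
    merged: list[GenomicInterval] = []
    for seg in loh:
        iv = seg.interval
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start <= merged[-1].end + 1
        ):
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    return merged


def hrd_loh_score(
    segments: Sequence[CopyNumberSegment],
    arms: Sequence[ArmDefinition],
    min_length_bp: int = 15 * MBP,
) -> int:
    """HRD-LOH score: subchromosomal LOH runs longer than ``min_length_bp``.

    A run spanning an entire chromosome (p-arm start through q-arm end, per
    the arm table) does not count — whole-chromosome LOH reflects
    aneuploidy, not the subchromosomal scarring of HRD.
    """
    by_chrom = arms_by_chrom(arms)
    score = 0
    for run in detect_loh(segments):
        if run.length <= min_length_bp:
            continue
        arm = by_chrom.get(run.chrom)
        if arm is not None and run.contains(arm.chrom_extent):
            continue  # whole-chromosome LOH is not subchromosomal
        score += 1
    return score


def _clip_to_arm(
    segments: Sequence[CopyNumberSegment], arm_iv: GenomicInterval
) -> list[CopyNumberSegment]:
    """Segments intersected with one arm (split at arm boundaries)."""
    out = []
    for seg in segments:
        iv = seg.interval
        if iv.chrom != arm_iv.chrom or iv.end < arm_iv.start or iv.start > arm_iv.end:
            continue
        clipped = GenomicInterval(
            iv.chrom, max(iv.start, arm_iv.start), min(iv.end, arm_iv.end)
        )
        out.append(CopyNumberSegment(clipped, seg.total_cn, seg.minor_cn))
    return out


def _smooth(
    segments: list[CopyNumberSegment], min_len_bp: float, allele_specific: bool
) -> list[tuple[tuple, int]]:
    """Merge same-state runs, drop runs shorter than min_len_bp, re-merge.

    Merging before the length filter makes the result invariant to
    splitting a segment into abutting same-state pieces. Returns
    (state, run_length) pairs in genomic order.
    """
    runs: list[tuple[tuple, int]] = []
    for seg in segments:
        state = seg.state(allele_specific)
        if runs and runs[-1][0] == state:
            runs[-1] = (state, runs[-1][1] + seg.interval.length)
        else:
            runs.append((state, seg.interval.length))
    smoothed: list[tuple[tuple, int]] = []
    for state, length in runs:
        if length < min_len_bp:
            continue
        if smoothed and smoothed[-1][0] == state:
            smoothed[-1] = (state, smoothed[-1][1] + length)
        else:
            smoothed.append((state, length))
    return smoothed


def lst_count(
    segments: Sequence[CopyNumberSegment],
    arms: Sequence[ArmDefinition],
    smooth_mbp: float = 3.0,
    min_flank_mbp: float = 10.0,
    allele_specific: bool = True,
) -> int:
    """Count large-scale state transitions (LSTs).

    Per arm: segments are clipped to the arm (a segment crossing the
    centromere is split at the boundary), segments shorter than
    ``smooth_mbp`` are dropped and flanking identical-state runs merged,
    then adjacent run pairs with different states where both runs are at
    least ``min_flank_mbp`` long are counted. Flanks never straddle the
    centromere. States are (total, minor) pairs by default; total-only with
    ``allele_specific=False``.
    """
    by_chrom = arms_by_chrom(arms)
    seg_chroms = {s.interval.chrom for s in segments}
    missing = seg_chroms - set(by_chrom)
    if missing:
        raise ValueError(f"no arm definition for chromosome(s): {sorted(missing)}")
    count = 0
    for chrom in sorted(seg_chroms):
        chrom_segs = sorted(
            (s for s in segments if s.interval.chrom == chrom),
            key=lambda s: s.interval.start,
        )
        for arm_iv in by_chrom[chrom].arms:
            runs = _smooth(
                _clip_to_arm(chrom_segs, arm_iv), smooth_mbp * MBP, allele_specific
            )
            for (state_a, len_a), (state_b, len_b) in zip(runs, runs[1:]):
                if (
                    state_a != state_b
                    and len_a >= min_flank_mbp * MBP
                    and len_b >= min_flank_mbp * MBP
                ):
                    count += 1
    return count


def compute_scar_metrics(
    segments: Sequence[CopyNumberSegment], arms: Sequence[ArmDefinition]
) -> ScarMetrics:
    """Bundle ploidy, HRD-LOH and LST for a profile."""
    return ScarMetrics(
        hrd_loh=hrd_loh_score(segments, arms),
        lst=lst_count(segments, arms),
        ploidy=ploidy(segments),
        segment_count=len(segments),
    )


def call_cna(
    gene_annotations: Mapping[str, GenomicInterval],
    segments: Sequence[CopyNumberSegment],
    avg_ploidy: float,
    amp_ploidy_factor: float = 2.0,
    amp_offset: float = 1.0,
) -> tuple[list[CNACall], list[str]]:
    """Ploidy-relative copy-number calls per gene.

    A gene overlapping several segments takes the length-weighted total CN
    over the overlap. Thresholds (default AMP iff CN >= 2*ploidy + 1): the
    same focal copy number of 6 is an amplification at ploidy 2 but only a
    gain at ploidy 4, because genome duplication inflates absolute copy
    numbers without implying selection.

    Returns (calls, uncovered_genes).
    """
    calls: list[CNACall] = []
    uncovered: list[str] = []
    for gene, gene_iv in gene_annotations.items():
        overlap_len = 0
        weighted_cn = 0.0
        min_total_state = None
        for seg in segments:
            if not seg.interval.overlaps(gene_iv):
                continue
            ov = (
                min(seg.interval.end, gene_iv.end)
                - max(seg.interval.start, gene_iv.start)
                + 1
            )
            overlap_len += ov
            weighted_cn += ov * seg.total_cn
            state = seg.total_state
            min_total_state = state if min_total_state is None else min(min_total_state, state)
        if overlap_len == 0:
            uncovered.append(gene)
            continue
        total_cn = weighted_cn / overlap_len
        state = round(total_cn)
        amp_threshold = amp_ploidy_factor * avg_ploidy + amp_offset
        if state == 0:
            call = CNACallType.HOMDEL
        elif total_cn >= amp_threshold:
            call = CNACallType.AMP
        elif total_cn > avg_ploidy:
            call = CNACallType.GAIN
        elif state < round(avg_ploidy) and state >= 1:
            call = CNACallType.HETLOSS
        else:
            call = CNACallType.NEUTRAL
        calls.append(CNACall(gene=gene, total_cn=total_cn, ploidy=avg_ploidy, call=call))
    return calls, uncovered


#: consequences accepted as a mutational second hit on the remaining allele
TRUNCATING_CONSEQUENCES = frozenset(
    {"frameshift", "stop_gained", "splice_donor", "splice_acceptor", "start_lost"}
)


def second_hit(
    gene: str,
    cna: CNACall,
    variants: Iterable = (),
    focal_events: Iterable[GenomicInterval] = (),
    loh_runs: Iterable[GenomicInterval] = (),
    gene_interval: GenomicInterval | None = None,
    pathogenic_genes: frozenset[str] | set[str] = frozenset(),
) -> tuple[SecondHit, bool]:
    """Second-hit assessment for a copy-number loss call.

    A HOMDEL is biallelic by definition. A HETLOSS is biallelic only when
    the remaining allele carries a truncating/pathogenic small variant, a
    focal intragenic deletion, or falls inside an LOH run; a lone
    heterozygous deletion of a tumor suppressor leaves functional
    consequences unclear and should be interpreted with caution.

    Returns (second-hit kind, biallelic-loss flag).
    """
    if cna.call not in (CNACallType.HETLOSS, CNACallType.HOMDEL):
        raise ValueError(f"second_hit applies to loss calls, got {cna.call}")
    if cna.call == CNACallType.HOMDEL:
        cna.second_hit = SecondHit.NONE
        return SecondHit.NONE, True
    for var in variants:
        if var.gene == gene and (
            var.consequence in TRUNCATING_CONSEQUENCES or gene in pathogenic_genes
        ):
            cna.second_hit = SecondHit.MUTATION
            return SecondHit.MUTATION, True
    if gene_interval is not None:
        for ev in focal_events:
            if ev.overlaps(gene_interval):
                cna.second_hit = SecondHit.FOCAL_INTRAGENIC_DELETION
                return SecondHit.FOCAL_INTRAGENIC_DELETION, True
        for run in loh_runs:
            if run.contains(gene_interval):
                cna.second_hit = SecondHit.LOH
                return SecondHit.LOH, True
    cna.second_hit = SecondHit.NONE
    return SecondHit.NONE, False
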