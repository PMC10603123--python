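"""Readers/writers for external formats, sample-intake QC, shared coordinates.

Internal coordinates are 1-based inclusive throughout the package (the VCF /
SEG habit); BED input is converted on read and converted back on write, so
``write(read(x)) == x`` for canonical files. Chromosome names are normalized
by stripping a leading ``chr``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class FormatError(ValueError):
    """A file violated its format contract (malformed row, bad invariant)."""


class NotComputableError(RuntimeError):
    """A metric cannot be computed from the given input (e.g. missing minor CN)."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so mixed-source inputs agree."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError(f"1-based coordinates start at 1, got {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class ArmDefinition:
    """p and q arm extents of one chromosome (1-based inclusive).

    The arms tile the chromosome except for the centromere gap:
    ``p_arm.end < q_arm.start``.
    """

    chrom: str
    p_arm: GenomicInterval
    q_arm: GenomicInterval

    def __post_init__(self) -> None:
        if self.p_arm.end >= self.q_arm.start:
            raise ValueError(
                f"{self.chrom}: p arm must end before q arm starts "
                f"({self.p_arm.end} >= {self.q_arm.start})"
            )

    @property
    def chrom_extent(self) -> GenomicInterval:
        """Whole-chromosome span, p start through q end."""
        return GenomicInterval(self.chrom, self.p_arm.start, self.q_arm.end)

    @property
    def arms(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.p_arm, self.q_arm)


class Assay(str, enum.Enum):
    WGS = "WGS"
    WES = "WES"


@dataclass
class SampleMeta:
    """Sample-level intake metadata used by the QC gate.

    tumor_cell_content is the pathologist's estimate (a fraction); purity is
    the optional upstream computational estimate. The QC gate uses the
    pathologist field.
    """

    sample_id: str
    entity: str
    assay: Assay
    tumor_cell_content: float
    tumor_coverage: float
    control_coverage: float
    rna_reads: float | None = None  # millions of reads; None = no RNA assayed
    purity: float | None = None
    ploidy_override: float | None = None

    def __post_init__(self) -> None:
        self.assay = Assay(self.assay)
        for name, value in (
            ("tumor_cell_content", self.tumor_cell_content),
            ("purity", self.purity),
        ):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name, value in (
            ("tumor_coverage", self.tumor_coverage),
            ("control_coverage", self.control_coverage),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")


@dataclass(frozen=True)
class QCThresholds:
    """Intake thresholds: 20% tumor cell content; coverage minima per assay
    (tumor WGS 80x / WES 120x, control WGS 40x / WES 80x); 30 M RNA reads."""

    min_tumor_cell_content: float = 0.20
    min_tumor_coverage: dict[Assay, float] = field(
        default_factory=lambda: {Assay.WGS: 80.0, Assay.WES: 120.0}
    )
    min_control_coverage: dict[Assay, float] = field(
        default_factory=lambda: {Assay.WGS: 40.0, Assay.WES: 80.0}
    )
    min_rna_reads: float = 30.0  # millions


@dataclass(frozen=True)
class QCCheckFailure:
    check: str
    observed: float
    threshold: float


@dataclass(frozen=True)
class QCResult:
    passed: bool
    failures: tuple[QCCheckFailure, ...]


def qc_gate(meta: SampleMeta, thresholds: QCThresholds | None = None) -> QCResult:
    """Apply the sample-intake QC gate.

    Passes iff every applicable check passes: tumor cell content, tumor and
    control coverage for the sample's assay, and RNA read count when RNA was
    assayed. Each failure records the check name, observed value and
    threshold. Monotone: raising any observed value never flips pass to fail.
    """
    thr = thresholds or QCThresholds()
    failures: list[QCCheckFailure] = []
    if meta.tumor_cell_content < thr.min_tumor_cell_content:
        failures.append(
            QCCheckFailure(
                "tumor_cell_content", meta.tumor_cell_content, thr.min_tumor_cell_content
            )
        )
    tumor_min = thr.min_tumor_coverage[meta.assay]
    if meta.tumor_coverage < tumor_min:
        failures.append(QCCheckFailure("tumor_coverage", meta.tumor_coverage, tumor_min))
    control_min = thr.min_control_coverage[meta.assay]
    if meta.control_coverage < control_min:
        failures.append(
            QCCheckFailure("control_coverage", meta.control_coverage, control_min)
        )
    if meta.rna_reads is not None and meta.rna_reads < thr.min_rna_reads:
        failures.append(QCCheckFailure("rna_reads", meta.rna_reads, thr.min_rna_reads))
    return QCResult(passed=not failures, failures=tuple(failures))


# ---------------------------------------------------------------------------
# Copy-number segment TSV (SEG-like: chrom, start, end, total_cn, minor_cn)
# ---------------------------------------------------------------------------

SEGMENT_COLUMNS = ("chrom", "start", "end", "total_cn", "minor_cn")


def read_segments(path: str | Path) -> list:
    """Read a SEG-like TSV into sorted, validated copy-number segments.

    The file is tab-separated with header columns chrom, start, end,
    total_cn and (optionally) minor_cn; when minor_cn is absent or empty,
    LOH-dependent metrics downstream report "not computable" rather than
    guessing. Segments are returned sorted by (chrom, start); overlapping
    segments within a chromosome or negative copy numbers raise FormatError
    naming the offending rows.
    """
    from mtb_interpret.scars import CopyNumberSegment

    path = Path(path)
    segments: list[CopyNumberSegment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ("chrom", "start", "end", "total_cn")
        for col in required:
            if col not in header:
                raise FormatError(f"{path}: missing required column {col!r}")
        idx = {name: header.index(name) for name in header}
        has_minor = "minor_cn" in idx
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < len(required):
                raise FormatError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                chrom = normalize_chrom(fields[idx["chrom"]])
                start = int(fields[idx["start"]])
                end = int(fields[idx["end"]])
                total_cn = float(fields[idx["total_cn"]])
                minor_raw = fields[idx["minor_cn"]] if has_minor else ""
                minor_cn = float(minor_raw) if minor_raw not in ("", "NA", ".") else None
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from exc
            if total_cn < 0:
                raise FormatError(f"{path}:{lineno}: negative total_cn {total_cn}")
            if minor_cn is not None and minor_cn < 0:
                raise FormatError(f"{path}:{lineno}: negative minor_cn {minor_cn}")
            if minor_cn is not None and minor_cn > total_cn:
                raise FormatError(
                    f"{path}:{lineno}: minor_cn {minor_cn} exceeds total_cn {total_cn}"
                )
            segments.append(
                CopyNumberSegment(
                    interval=GenomicInterval(chrom, start, end),
                    total_cn=total_cn,
                    minor_cn=minor_cn,
                )
            )
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    _check_non_overlapping(segments, path)
    return segments


def _check_non_overlapping(segments: Sequence, path: str | Path) -> None:
    for prev, cur in zip(segments, segments[1:]):
        if prev.interval.overlaps(cur.interval):
            raise FormatError(
                f"{path}: overlapping segments "
                f"{prev.interval.chrom}:{prev.interval.start}-{prev.interval.end} and "
                f"{cur.interval.chrom}:{cur.interval.start}-{cur.interval.end}"
            )


def write_segments(segments: Iterable, path: str | Path) -> None:
    """Write segments as the SEG-like TSV that read_segments accepts."""
    with open(path, "w") as fh:
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for seg in segments:
            minor = "" if seg.minor_cn is None else _fmt_cn(seg.minor_cn)
            fh.write(
                f"{seg.interval.chrom}\t{seg.interval.start}\t{seg.interval.end}\t"
                f"{_fmt_cn(seg.total_cn)}\t{minor}\n"
            )


def _fmt_cn(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(value)


# ---------------------------------------------------------------------------
# Chromosome-arm BED (0-based half-open, 4th column "1p"/"1q" style labels)
# ---------------------------------------------------------------------------


def read_arms(path: str | Path) -> list[ArmDefinition]:
    """Read a BED4 arm table into per-chromosome arm definitions.

    BED coordinates (0-based, half-open) are converted to the package's
    1-based inclusive convention. Every chromosome must contribute both a p
    and a q arm; a lone arm raises FormatError.
    """
    path = Path(path)
    arms: dict[str, dict[str, GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: BED4 row needs 4 columns")
            chrom = normalize_chrom(fields[0])
            start0, end0 = int(fields[1]), int(fields[2])
            label = fields[3]
            arm_letter = label[-1]
            if arm_letter not in ("p", "q"):
                raise FormatError(f"{path}:{lineno}: arm label must end in p or q")
            interval = GenomicInterval(chrom, start0 + 1, end0)
            arms.setdefault(chrom, {})[arm_letter] = interval
    result = []
    for chrom, parts in arms.items():
        if set(parts) != {"p", "q"}:
            raise FormatError(
                f"{path}: chromosome {chrom} has only arm(s) {sorted(parts)}; "
                "both p and q are required"
            )
        result.append(ArmDefinition(chrom=chrom, p_arm=parts["p"], q_arm=parts["q"]))
    result.sort(key=lambda a: a.chrom)
    return result


def write_arms(arms: Iterable[ArmDefinition], path: str | Path) -> None:
    """Write arm definitions back out as BED4 (0-based half-open)."""
    with open(path, "w") as fh:
        for arm in sorted(arms, key=lambda a: a.chrom):
            for letter, iv in (("p", arm.p_arm), ("q", arm.q_arm)):
                fh.write(f"{arm.chrom}\t{iv.start - 1}\t{iv.end}\t{arm.chrom}{letter}\n")


def arms_by_chrom(arms: Iterable[ArmDefinition]) -> dict[str, ArmDefinition]:
    return {a.chrom: a for a in arms}
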