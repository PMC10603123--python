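"""Deterministic synthetic-data generators for every analysis layer.

Each generator is a pure function of its spec and seed and returns a
manifest of ground truth computed *by construction* — independent of the
production analysis code — so tests can compare implementation output
against what the generator knows it built. A small toy genome (three
chromosomes, 450 Mbp) keeps everything fast.

Profile kinds emulate the copy-number archetypes seen across tumor types:
a near-diploid "silent" genome (fusion-driven sarcoma-like), a highly
rearranged HRD-scarred genome (LOH runs straddling the 15-Mbp threshold,
many 10-30 Mbp state switches), and a focally amplified genome
(MDM2/CDK4-style amplicon on an otherwise quiet background).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mtb_interpret.core_io import ArmDefinition, GenomicInterval, write_arms, write_segments
from mtb_interpret.fusions import (
    FusionEvent,
    ProteinDomain,
    TranscriptModel,
)
from mtb_interpret.scars import MBP, CopyNumberSegment
from mtb_interpret.signatures import (
    CONTEXT_LABELS,
    SignatureMatrix,
    revcomp,
)
from mtb_interpret.small_variants import SmallVariant, VariantType

# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

#: centromere gap width between p-arm end and q-arm start
CENTROMERE_GAP = 3 * MBP


@dataclass(frozen=True)
class ToyChromosome:
    name: str
    length: int
    p_end: int  # last base of the p arm

    @property
    def q_start(self) -> int:
        return self.p_end + CENTROMERE_GAP + 1


@dataclass(frozen=True)
class ToyGenome:
    chromosomes: tuple[ToyChromosome, ...] = (
        ToyChromosome("1", 200 * MBP, 90 * MBP),
        ToyChromosome("2", 150 * MBP, 60 * MBP),
        ToyChromosome("3", 100 * MBP, 40 * MBP),
    )

    def arms(self) -> list[ArmDefinition]:
        return [
            ArmDefinition(
                chrom=c.name,
                p_arm=GenomicInterval(c.name, 1, c.p_end),
                q_arm=GenomicInterval(c.name, c.q_start, c.length),
            )
            for c in self.chromosomes
        ]


class ProfileKind(str, enum.Enum):
    SILENT = "SILENT"
    HRD_LIKE = "HRD_LIKE"
    AMPLIFIED_12Q_LIKE = "AMPLIFIED_12q_LIKE"


class FusionScenario(str, enum.Enum):
    OUT_OF_FRAME_KINASE = "OUT_OF_FRAME_KINASE"
    IN_FRAME_KINASE = "IN_FRAME_KINASE"
    PROMOTER_SWAP = "PROMOTER_SWAP"


@dataclass
class FixtureSpec:
    seed: int = 1
    profile_kind: ProfileKind = ProfileKind.HRD_LIKE
    n_snvs: int = 1000
    signature_mix: dict[str, float] = field(default_factory=lambda: {"SBS-A": 1.0})

    def __post_init__(self) -> None:
        self.profile_kind = ProfileKind(self.profile_kind)
        total = sum(self.signature_mix.values())
        if self.signature_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"signature mix weights must sum to 1, got {total}")


# ---------------------------------------------------------------------------
# Copy-number profiles
# ---------------------------------------------------------------------------

#: (total, minor) states with heterozygosity retained
_NON_LOH_STATES = ((2, 1), (3, 1), (4, 2), (4, 1))
#: LOH states: one parental allele lost, the other retained
_LOH_STATES = ((1, 0), (2, 0), (3, 0))


@dataclass
class SegmentFixture:
    segments: list[CopyNumberSegment]
    arms: list[ArmDefinition]
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        seg_path = out / "segments.tsv"
        arm_path = out / "arms.bed"
        write_segments(self.segments, seg_path)
        write_arms(self.arms, arm_path)
        return {"segments": seg_path, "arms": arm_path}


def _arm_pieces_to_segments(
    chrom: str, arm_start: int, pieces: Sequence[tuple[int, int, int]]
) -> list[CopyNumberSegment]:
    """Lay (length, total, minor) pieces end-to-end from arm_start."""
    segments = []
    pos = arm_start
    for length, total, minor in pieces:
        segments.append(
            CopyNumberSegment(
                GenomicInterval(chrom, pos, pos + length - 1),
                float(total),
                float(minor),
            )
        )
        pos += length
    return segments


def _true_lst_of_arm(pieces: Sequence[tuple[int, int, int]]) -> int:
    """Construction-side LST count for one arm's piece list.

    Merges identical neighbouring states, drops sub-3-Mbp runs, re-merges,
    then counts switches with both flanks >= 10 Mbp. Operates purely on the
    generator's internal representation.
    """
    runs: list[tuple[tuple[int, int], int]] = []
    for length, total, minor in pieces:
        state = (total, minor)
        if runs and runs[-1][0] == state:
            runs[-1] = (state, runs[-1][1] + length)
        else:
            runs.append((state, length))
    smoothed: list[tuple[tuple[int, int], int]] = []
    for state, length in runs:
        if length < 3 * MBP:
            continue
        if smoothed and smoothed[-1][0] == state:
            smoothed[-1] = (state, smoothed[-1][1] + length)
        else:
            smoothed.append((state, length))
    return sum(
        1
        for (sa, la), (sb, lb) in zip(smoothed, smoothed[1:])
        if sa != sb and la >= 10 * MBP and lb >= 10 * MBP
    )


def _true_hrd_runs(
    per_arm: Mapping[tuple[str, str], Sequence[tuple[int, int, int]]],
    whole_chrom_loh: Sequence[str] = (),
) -> int:
    """Construction-side HRD-LOH count: within-arm LOH runs > 15 Mbp.

    Arms are separated by the centromere gap and whole-chromosome LOH
    chromosomes are excluded (subchromosomal rule), so runs never span arms.
    """
    count = 0
    for (chrom, _arm), pieces in per_arm.items():
        if chrom in whole_chrom_loh:
            continue
        run_len = 0
        for length, total, minor in pieces:
            if minor == 0 and total >= 1:
                run_len += length
            else:
                if run_len > 15 * MBP:
                    count += 1
                run_len = 0
        if run_len > 15 * MBP:
            count += 1
    return count


def gen_segments(spec: FixtureSpec, genome: ToyGenome | None = None) -> SegmentFixture:
    """Generate a copy-number profile with a ground-truth manifest.

    The manifest records the true HRD-LOH and LST counts, computed from the
    generator's own piece lists, plus the length-weighted ploidy.
    """
    genome = genome or ToyGenome()
    rng = np.random.default_rng(spec.seed)
    kind = spec.profile_kind
    per_arm: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    whole_chrom_loh: list[str] = []
    segments: list[CopyNumberSegment] = []

    if kind is ProfileKind.SILENT:
        # near-diploid; a single small gained region on 2q
        for c in genome.chromosomes:
            p_len = c.p_end
            q_len = c.length - c.q_start + 1
            per_arm[(c.name, "p")] = [(p_len, 2, 1)]
            if c.name == "2":
                per_arm[(c.name, "q")] = [
                    (q_len - 8 * MBP, 2, 1),
                    (8 * MBP, 3, 1),
                ]
            else:
                per_arm[(c.name, "q")] = [(q_len, 2, 1)]
    elif kind is ProfileKind.AMPLIFIED_12Q_LIKE:
        # near-diploid with a 2-Mbp high-level amplicon inside 2q
        for c in genome.chromosomes:
            p_len = c.p_end
            q_len = c.length - c.q_start + 1
            per_arm[(c.name, "p")] = [(p_len, 2, 1)]
            if c.name == "2":
                flank = (q_len - 2 * MBP) // 2
                per_arm[(c.name, "q")] = [
                    (flank, 2, 1),
                    (2 * MBP, 8, 1),
                    (q_len - flank - 2 * MBP, 2, 1),
                ]
            else:
                per_arm[(c.name, "q")] = [(q_len, 2, 1)]
    elif kind is ProfileKind.HRD_LIKE:
        # chromosomes 1 and 2: alternating LOH / heterozygous blocks with
        # lengths straddling both the 15-Mbp LOH and 10-Mbp LST thresholds
        for c in genome.chromosomes[:2]:
            for arm_name, arm_len in (
                ("p", c.p_end),
                ("q", c.length - c.q_start + 1),
            ):
                pieces: list[tuple[int, int, int]] = []
                remaining = arm_len
                is_loh_block = bool(rng.integers(0, 2))
                prev_state: tuple[int, int] | None = None
                while remaining > 0:
                    length = int(rng.integers(5, 33)) * MBP
                    length = min(length, remaining)
                    pool = _LOH_STATES if is_loh_block else _NON_LOH_STATES
                    choices = [s for s in pool if s != prev_state]
                    state = choices[int(rng.integers(0, len(choices)))]
                    pieces.append((length, state[0], state[1]))
                    prev_state = state
                    remaining -= length
                    is_loh_block = not is_loh_block
                per_arm[(c.name, arm_name)] = pieces
        # chromosome 3: whole-chromosome LOH (one segment spanning the
        # centromere) — a scar the subchromosomal rule must NOT count
        c3 = genome.chromosomes[2]
        whole_chrom_loh.append(c3.name)
        segments.append(
            CopyNumberSegment(GenomicInterval(c3.name, 1, c3.length), 1.0, 0.0)
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown profile kind {kind}")

    arms = genome.arms()
    arm_lookup = {(a.chrom, "p"): a.p_arm for a in arms}
    arm_lookup.update({(a.chrom, "q"): a.q_arm for a in arms})
    for (chrom, arm_name), pieces in sorted(per_arm.items()):
        arm_iv = arm_lookup[(chrom, arm_name)]
        segments.extend(_arm_pieces_to_segments(chrom, arm_iv.start, pieces))
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))

    total_len = sum(s.interval.length for s in segments)
    true_ploidy = sum(s.interval.length * s.total_cn for s in segments) / total_len
    true_lst = sum(_true_lst_of_arm(p) for p in per_arm.values())
    true_hrd = _true_hrd_runs(per_arm, whole_chrom_loh)
    manifest = {
        "profile_kind": kind.value,
        "seed": spec.seed,
        "hrd_loh": true_hrd,
        "lst": true_lst,
        "ploidy": true_ploidy,
        "segment_count": len(segments),
        "whole_chromosome_loh": whole_chrom_loh,
    }
    return SegmentFixture(segments=segments, arms=arms, manifest=manifest)


# ---------------------------------------------------------------------------
# Fixture signature spectra
# ---------------------------------------------------------------------------


def fixture_signatures() -> SignatureMatrix:
    """Two synthetic SBS-96 spectra with partially disjoint support.

    SBS-A weights the C>* classes, SBS-B the T>* classes, with a shared
    overlap region so refitting is a genuine (but well-conditioned)
    deconvolution rather than trivial bin assignment. Not COSMIC copies.
    """
    a = np.zeros(96)
    b = np.zeros(96)
    # bins 0-47 are C>A/C>G/C>T; 48-95 are T>A/T>C/T>G
    a[0:48] = 1.5
    a[48:64] = 0.25  # overlap into T>A
    b[32:48] = 0.25  # overlap into C>T
    b[48:96] = 1.5
    a /= a.sum()
    b /= b.sum()
    return SignatureMatrix(matrix=np.column_stack([a, b]), names=("SBS-A", "SBS-B"))


# ---------------------------------------------------------------------------
# SNV / VCF generation
# ---------------------------------------------------------------------------


@dataclass
class SNVFixture:
    variants: list[SmallVariant]
    contexts: dict[str, str]  # "chrom:pos" -> reference-strand trinucleotide
    true_exposures: dict[str, float]
    true_catalog: np.ndarray  # 96-vector of drawn counts

    def write_vcf(self, path: str | Path) -> Path:
        path = Path(path)
        with_control = any(v.control_af is not None for v in self.variants)
        with open(path, "w") as fh:
            fh.write(_vcf_header(with_control))
            for var in self.variants:
                depth = 100
                alt_reads = int(round(var.dna_af * depth))
                ctrl = ""
                if var.control_af is not None:
                    c_alt = int(round(var.control_af * depth))
                    ctrl = f"\t{depth - c_alt},{c_alt}"
                fh.write(
                    f"{var.interval.chrom}\t{var.interval.start}\t.\t{var.ref}\t"
                    f"{var.alt}\t.\tPASS\tGENE={var.gene};CSQ={var.consequence}\t"
                    f"AD\t{depth - alt_reads},{alt_reads}{ctrl}\n"
                )
        return path

    def write_contexts(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("variant\tcontext\n")
            for key, ctx in self.contexts.items():
                fh.write(f"{key}\t{ctx}\n")
        return path


def _vcf_header(with_control: bool = True) -> str:
    samples = "TUMOR\tCONTROL" if with_control else "TUMOR"
    return (
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n'
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        "##contig=<ID=1,length=200000000>\n"
        "##contig=<ID=2,length=150000000>\n"
        "##contig=<ID=3,length=100000000>\n"
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n"
    )


def _parse_label(label: str) -> tuple[str, str, str]:
    """'A[C>T]G' -> (trinucleotide 'ACG', ref 'C', alt 'T')."""
    five, rest = label[0], label[2:]
    sub, three = rest[:3], rest[4]
    ref, alt = sub[0], sub[2]
    return five + ref + three, ref, alt


def gen_snvs(
    spec: FixtureSpec,
    signatures: SignatureMatrix | None = None,
    with_control: bool = False,
) -> SNVFixture:
    """Draw SNVs whose trinucleotide contexts follow a signature mixture.

    Contexts are drawn multinomially from S . e, where e is the requested
    mixture; the drawn per-bin counts and the true mixture are recorded in
    the fixture. About half the variants are emitted on the purine
    reference strand to exercise strand collapsing downstream.
    """
    signatures = signatures or fixture_signatures()
    rng = np.random.default_rng(spec.seed)
    weights = np.zeros(signatures.k)
    for name, w in spec.signature_mix.items():
        weights[signatures.names.index(name)] = w
    probs = signatures.matrix @ weights
    probs = probs / probs.sum()
    counts = (
        rng.multinomial(spec.n_snvs, probs)
        if spec.n_snvs > 0
        else np.zeros(96, dtype=int)
    )

    variants: list[SmallVariant] = []
    contexts: dict[str, str] = {}
    chroms = ("1", "2", "3")
    pos_counter = {c: 10_000 for c in chroms}
    for bin_i, bin_count in enumerate(counts):
        label = CONTEXT_LABELS[bin_i]
        tri, ref, alt = _parse_label(label)
        for _ in range(bin_count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = pos_counter[chrom]
            pos_counter[chrom] += int(rng.integers(50, 500))
            if rng.random() < 0.5:  # represent on the purine strand
                var_ref, var_alt, var_tri = revcomp(ref), revcomp(alt), revcomp(tri)
            else:
                var_ref, var_alt, var_tri = ref, alt, tri
            key = f"{chrom}:{pos}"
            contexts[key] = var_tri
            variants.append(
                SmallVariant(
                    gene="unknown",
                    hgvs_p="",
                    interval=GenomicInterval(chrom, pos, pos),
                    ref=var_ref,
                    alt=var_alt,
                    variant_type=VariantType.SNV,
                    consequence="missense",
                    dna_af=float(np.clip(rng.normal(0.4, 0.1), 0.05, 0.95)),
                    control_af=0.0 if with_control else None,
                )
            )
    variants.sort(key=lambda v: (v.interval.chrom, v.interval.start))
    return SNVFixture(
        variants=variants,
        contexts=contexts,
        true_exposures=dict(spec.signature_mix),
        true_catalog=counts.astype(float),
    )


# ---------------------------------------------------------------------------
# Fusion scenarios
# ---------------------------------------------------------------------------


def _codons_without_stop(n: int, pattern: str = "GCT") -> str:
    return pattern * n


@dataclass
class FusionFixture:
    event: FusionEvent
    model5: TranscriptModel
    model3: TranscriptModel
    expected_frame: str
    expected_classification: str
    # explicit nucleotide bookkeeping for the translation oracle
    seq5_retained: str  # coding bases of the 5' gene retained at the junction
    seq3_retained: str  # coding bases of the 3' gene downstream of the junction
    l5: int
    u3: int


def _plus_strand_model(
    gene: str,
    chrom: str,
    domains: tuple[ProteinDomain, ...] = (),
    cds_start: int = 1300,
    cds_end: int = 7699,
) -> TranscriptModel:
    return TranscriptModel(
        gene=gene,
        chrom=chrom,
        strand="+",
        exons=(
            GenomicInterval(chrom, 1000, 1999),
            GenomicInterval(chrom, 4000, 4999),
            GenomicInterval(chrom, 7000, 7999),
        ),
        cds_start=cds_start,
        cds_end=cds_end,
        domains=domains,
    )


def _fgfr1_model() -> TranscriptModel:
    """Minus-strand kinase gene: 2400-nt CDS (800 aa), kinase domain
    aa 400-700 spanning beyond exon 2."""
    chrom = "8"
    return TranscriptModel(
        gene="FGFR1",
        chrom=chrom,
        strand="-",
        exons=(
            GenomicInterval(chrom, 9000, 9999),
            GenomicInterval(chrom, 6000, 6999),
            GenomicInterval(chrom, 3000, 3999),
        ),
        cds_start=9699,
        cds_end=3300,
        domains=(ProteinDomain("protein kinase", 400, 700, is_kinase=True),),
    )


def gen_fusion_case(scenario: FusionScenario | str) -> FusionFixture:
    """Engineer one fusion scenario with explicit nucleotide bookkeeping.

    The retained coding sequences are constructed so that translating
    through the junction is stop-free exactly when the junction is in
    frame: the 3' sequence carries a codon-aligned TTA-ATT-AAG motif that
    reads as Leu-Ile-Lys in frame but yields a TAA stop in either shifted
    frame.
    """
    scenario = FusionScenario(scenario)
    if scenario is FusionScenario.IN_FRAME_KINASE:
        # FGFR2 exons 1-2 (kinase domain inside) fused in frame to WDR65
        model5 = _plus_strand_model(
            "FGFR2",
            "10",
            domains=(ProteinDomain("protein kinase", 200, 500, is_kinase=True),),
        )
        model3 = _plus_strand_model("WDR65", "1", cds_start=1500, cds_end=7799)
        event = FusionEvent(
            gene5="FGFR2",
            gene3="WDR65",
            chrom5="10",
            breakpoint5=4999,  # end of FGFR2 exon 2: L5 = 700 + 1000 = 1700
            chrom3="1",
            breakpoint3=4000,  # start of WDR65 exon 2: U3 = 500
            split_reads=14,
            discordant_mates=6,
        )
        l5, u3 = 1700, 500
        expected_frame, expected_cls = "IN_FRAME", "ACTIONABLE_KINASE_FUSION"
    elif scenario is FusionScenario.OUT_OF_FRAME_KINASE:
        # FGFR1 exons 1-2 (kinase domain truncated) fused out of frame
        model5 = _fgfr1_model()
        model3 = _plus_strand_model("ADAM9", "8", cds_start=1400, cds_end=4899)
        # ADAM9 model here has exon CDS 600 + 1000 + 899; only the first two
        # exons matter for the junction arithmetic
        event = FusionEvent(
            gene5="FGFR1",
            gene3="ADAM9",
            chrom5="8",
            breakpoint5=6000,  # transcript end of FGFR1 exon 2: L5 = 1700
            chrom3="8",
            breakpoint3=4000,  # start of ADAM9 exon 2: U3 = 600
            split_reads=2,
            discordant_mates=0,
        )
        l5, u3 = 1700, 600
        expected_frame, expected_cls = "OUT_OF_FRAME", "NON_FUNCTIONAL"
    elif scenario is FusionScenario.PROMOTER_SWAP:
        # breakpoints between promoter and transcription start of both
        # partners: full-length PLAG1 under the FGFR1 promoter
        model5 = _fgfr1_model()
        chrom = "8"
        model3 = TranscriptModel(
            gene="PLAG1",
            chrom=chrom,
            strand="+",
            exons=(
                GenomicInterval(chrom, 20000, 20999),
                GenomicInterval(chrom, 23000, 23999),
            ),
            cds_start=20300,
            cds_end=23899,
        )
        event = FusionEvent(
            gene5="FGFR1",
            gene3="PLAG1",
            chrom5=chrom,
            breakpoint5=10500,  # upstream of FGFR1 TSS (minus strand)
            chrom3=chrom,
            breakpoint3=19500,  # upstream of PLAG1 TSS
            split_reads=9,
            discordant_mates=4,
        )
        l5, u3 = 0, 0
        expected_frame, expected_cls = "PROMOTER_SWAP", "ONCOGENIC_NOT_DRUGGABLE"
    else:  # pragma: no cover
        raise ValueError(f"unknown scenario {scenario}")

    seq5_retained, seq3_retained = _junction_sequences(model3, l5, u3)
    return FusionFixture(
        event=event,
        model5=model5,
        model3=model3,
        expected_frame=expected_frame,
        expected_classification=expected_cls,
        seq5_retained=seq5_retained,
        seq3_retained=seq3_retained,
        l5=l5,
        u3=u3,
    )


def _junction_sequences(model3: TranscriptModel, l5: int, u3: int) -> tuple[str, str]:
    """Engineered coding sequences around the junction.

    The 5' retained part is a start codon plus stop-free codons, trimmed to
    l5 bases. The 3' gene's full CDS is stop-free codons with the
    frame-sensitive TTAATTAAG motif placed codon-aligned shortly after the
    breakpoint; the retained part is the suffix from offset u3.
    """
    if l5 == 0:
        return "", ""
    full5 = "ATG" + _codons_without_stop((l5 // 3) + 2)
    seq5 = full5[:l5]
    cds3_len = model3.cds_length
    n_codons3 = cds3_len // 3
    # place the motif 12 codons after the first fully retained codon
    motif_codon = u3 // 3 + (1 if u3 % 3 == 0 else 2) + 12
    codons3 = ["GAA"] * (n_codons3 + 1)
    codons3[motif_codon - 1 : motif_codon + 2] = ["TTA", "ATT", "AAG"]
    full3 = "".join(codons3)[:cds3_len]
    return seq5, full3[u3:]
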