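"""Copy-number scar metrics against hand traces and the array-scan oracle."""

import pytest

from conftest import MBP, oracle_hrd_loh, oracle_lst, oracle_ploidy
from mtb_interpret import fixtures as fx
from mtb_interpret.core_io import ArmDefinition, GenomicInterval, NotComputableError
from mtb_interpret.scars import (
    CNACall,
    CNACallType,
    CopyNumberSegment,
    SecondHit,
    call_cna,
    detect_loh,
    hrd_loh_score,
    lst_count,
    ploidy,
    second_hit,
)
from mtb_interpret.small_variants import SmallVariant, VariantType


def seg(chrom, start_mbp, end_mbp, total, minor=None):
    return CopyNumberSegment(
        GenomicInterval(chrom, int(start_mbp * MBP) + 1, int(end_mbp * MBP)),
        float(total),
        None if minor is None else float(minor),
    )


def one_chrom_arms(chrom="1", p_end_mbp=90, length_mbp=200):
    return [
        ArmDefinition(
            chrom,
            GenomicInterval(chrom, 1, p_end_mbp * MBP),
            GenomicInterval(chrom, (p_end_mbp + 3) * MBP + 1, length_mbp * MBP),
        )
    ]


class TestPloidy:
    def test_single_segment_is_its_copy_number(self):
        assert ploidy([seg("1", 0, 10, 2, 1)]) == 2.0

    def test_equal_lengths_average(self):
        assert ploidy([seg("1", 0, 10, 2, 1), seg("1", 10, 20, 4, 1)]) == 3.0

    def test_length_weighting(self):
        # 30 Mbp at CN 2 and 10 Mbp at CN 6 -> (60 + 60) / 40 = 3
        assert ploidy([seg("1", 0, 30, 2, 1), seg("1", 30, 40, 6, 2)]) == 3.0

    def test_sex_chromosomes_excluded(self):
        assert ploidy([seg("1", 0, 10, 2, 1), seg("X", 0, 50, 1, 0)]) == 2.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ploidy([])

    def test_fixture_profile_matches_brute_force(self, segment_fixture):
        assert ploidy(segment_fixture.segments) == pytest.approx(
            oracle_ploidy(segment_fixture.segments)
        )

    def test_uniform_scaling_scales_ploidy(self, segment_fixture):
        doubled = [
            CopyNumberSegment(s.interval, s.total_cn * 2, s.minor_cn)
            for s in segment_fixture.segments
        ]
        assert ploidy(doubled) == pytest.approx(2 * ploidy(segment_fixture.segments))


class TestDetectLOH:
    def test_minor_zero_total_one_is_loh(self):
        runs = detect_loh([seg("1", 0, 20, 1, 0)])
        assert runs == [GenomicInterval("1", 1, 20 * MBP)]

    def test_homozygous_deletion_is_not_loh(self):
        assert detect_loh([seg("1", 0, 20, 0, 0)]) == []

    def test_abutting_runs_merge(self):
        runs = detect_loh([seg("1", 0, 10, 1, 0), seg("1", 10, 25, 2, 0)])
        assert runs == [GenomicInterval("1", 1, 25 * MBP)]

    def test_gap_prevents_merge(self):
        runs = detect_loh([seg("1", 0, 10, 1, 0), seg("1", 50, 70, 1, 0)])
        assert len(runs) == 2

    def test_missing_minor_cn_not_computable(self):
        with pytest.raises(NotComputableError):
            detect_loh([seg("1", 0, 20, 2)])


class TestHRDLOH:
    def test_20mbp_run_on_large_chromosome_counts(self):
        segs = [seg("1", 0, 20, 1, 0), seg("1", 20, 90, 2, 1)]
        assert hrd_loh_score(segs, one_chrom_arms()) == 1

    def test_sub_threshold_run_does_not_count(self):
        segs = [
            CopyNumberSegment(GenomicInterval("1", 1, 14_900_000), 1.0, 0.0),
            CopyNumberSegment(GenomicInterval("1", 14_900_001, 90 * MBP), 2.0, 1.0),
        ]
        assert hrd_loh_score(segs, one_chrom_arms()) == 0

    def test_exactly_15mbp_does_not_count(self):
        segs = [seg("1", 0, 15, 1, 0), seg("1", 15, 90, 2, 1)]
        assert hrd_loh_score(segs, one_chrom_arms()) == 0

    def test_whole_chromosome_loh_excluded(self):
        segs = [seg("1", 0, 200, 1, 0)]
        assert hrd_loh_score(segs, one_chrom_arms()) == 0

    def test_threshold_monotonicity(self, segment_fixture):
        scores = [
            hrd_loh_score(segment_fixture.segments, segment_fixture.arms, t * MBP)
            for t in (5, 10, 15, 20, 30)
        ]
        assert scores == sorted(scores, reverse=True)


class TestLST:
    def test_uniform_arm_has_no_transitions(self):
        segs = [seg("1", 0, 90, 2, 1)]
        assert lst_count(segs, one_chrom_arms()) == 0

    def test_single_switch_with_long_flanks(self):
        segs = [seg("1", 0, 12, 2, 1), seg("1", 12, 24, 3, 1)]
        assert lst_count(segs, one_chrom_arms()) == 1

    def test_short_flank_not_counted(self):
        segs = [seg("1", 0, 9, 2, 1), seg("1", 9, 24, 3, 1)]
        assert lst_count(segs, one_chrom_arms()) == 0

    def test_small_spike_smoothed_away(self):
        # 2-Mbp spike inside a uniform arm: flanks merge, no transition
        segs = [seg("1", 0, 40, 2, 1), seg("1", 40, 42, 8, 1), seg("1", 42, 90, 2, 1)]
        assert lst_count(segs, one_chrom_arms()) == 0

    def test_allele_specific_switch_with_constant_total(self):
        # copy-neutral LOH boundary: total 2 both sides, minor 1 vs 0
        segs = [seg("1", 0, 20, 2, 1), seg("1", 20, 40, 2, 0)]
        assert lst_count(segs, one_chrom_arms()) == 1
        assert lst_count(segs, one_chrom_arms(), allele_specific=False) == 0

    def test_centromere_spanning_segment_split_and_silent(self):
        segs = [seg("1", 0, 200, 2, 1)]
        assert lst_count(segs, one_chrom_arms()) == 0

    def test_missing_arm_definition_rejected(self):
        with pytest.raises(ValueError, match="no arm definition"):
            lst_count([seg("7", 0, 20, 2, 1)], one_chrom_arms())

    def test_split_invariance(self, segment_fixture):
        """Splitting any segment into two abutting same-state halves is a no-op."""
        segs = segment_fixture.segments
        arms = segment_fixture.arms
        base = lst_count(segs, arms)
        for idx in (0, len(segs) // 2, len(segs) - 1):
            s = segs[idx]
            if s.interval.length < 2:
                continue
            mid = s.interval.start + s.interval.length // 2
            split = (
                segs[:idx]
                + [
                    CopyNumberSegment(
                        GenomicInterval(s.interval.chrom, s.interval.start, mid),
                        s.total_cn,
                        s.minor_cn,
                    ),
                    CopyNumberSegment(
                        GenomicInterval(s.interval.chrom, mid + 1, s.interval.end),
                        s.total_cn,
                        s.minor_cn,
                    ),
                ]
                + segs[idx + 1 :]
            )
            assert lst_count(split, arms) == base

    def test_flank_threshold_monotonicity(self, segment_fixture):
        counts = [
            lst_count(segment_fixture.segments, segment_fixture.arms, min_flank_mbp=f)
            for f in (3, 5, 10, 15, 25)
        ]
        assert counts == sorted(counts, reverse=True)


class TestOracleAgreement:
    """Production metrics equal an exhaustive per-Mbp array scan."""

    def test_hrd_loh_matches_oracle(self, segment_fixture, toy_genome):
        assert hrd_loh_score(
            segment_fixture.segments, segment_fixture.arms
        ) == oracle_hrd_loh(segment_fixture.segments, toy_genome)

    def test_lst_matches_oracle(self, segment_fixture, toy_genome):
        assert lst_count(segment_fixture.segments, segment_fixture.arms) == oracle_lst(
            segment_fixture.segments, toy_genome
        )

    def test_metrics_match_construction_manifest(self, segment_fixture):
        m = segment_fixture.manifest
        assert hrd_loh_score(segment_fixture.segments, segment_fixture.arms) == m["hrd_loh"]
        assert lst_count(segment_fixture.segments, segment_fixture.arms) == m["lst"]
        assert ploidy(segment_fixture.segments) == pytest.approx(m["ploidy"])


GENE = {"MDM2": GenomicInterval("2", 94 * MBP + 1, 94 * MBP + 100_000)}


class TestCallCNA:
    def make(self, cn, pl):
        segs = [seg("1", 0, 100, cn, 0 if cn < 2 else 1)]
        genes = {"G": GenomicInterval("1", 10 * MBP, 10 * MBP + 50_000)}
        (call,), uncovered = call_cna(genes, segs, pl)
        assert not uncovered
        return call.call

    def test_cn8_ploidy2_is_amplification(self):
        assert self.make(8, 2.0) is CNACallType.AMP

    def test_cn6_ploidy4_is_gain_not_amp(self):
        assert self.make(6, 4.0) is CNACallType.GAIN

    def test_cn6_ploidy2_is_amplification(self):
        assert self.make(6, 2.0) is CNACallType.AMP

    def test_cn0_is_homozygous_deletion(self):
        assert self.make(0, 2.0) is CNACallType.HOMDEL

    def test_cn1_ploidy2_is_hetloss(self):
        assert self.make(1, 2.0) is CNACallType.HETLOSS

    def test_cn3_ploidy4_is_hetloss(self):
        assert self.make(3, 4.0) is CNACallType.HETLOSS

    def test_uncovered_gene_flagged(self):
        segs = [seg("1", 0, 100, 2, 1)]
        calls, uncovered = call_cna(
            {"G": GenomicInterval("9", 1, 1000)}, segs, 2.0
        )
        assert calls == [] and uncovered == ["G"]

    def test_multi_segment_gene_takes_weighted_cn(self):
        segs = [seg("1", 0, 10, 2, 1), seg("1", 10, 20, 6, 1)]
        genes = {"G": GenomicInterval("1", 8 * MBP + 1, 12 * MBP)}
        (call,), _ = call_cna(genes, segs, 2.0)
        assert call.total_cn == pytest.approx(4.0)  # 2 Mbp at 2, 2 Mbp at 6


def _variant(gene="PTEN", consequence="frameshift"):
    return SmallVariant(
        gene=gene,
        hgvs_p="p.X1fs",
        interval=GenomicInterval("10", 1000, 1000),
        ref="A",
        alt="AT",
        variant_type=VariantType.INS,
        consequence=consequence,
        dna_af=0.4,
    )


class TestSecondHit:
    PTEN = GenomicInterval("10", 89_000_000, 89_100_000)

    def hetloss(self):
        return CNACall("PTEN", 1.0, 2.0, CNACallType.HETLOSS)

    def test_homdel_is_biallelic(self):
        cna = CNACall("PTEN", 0.0, 2.0, CNACallType.HOMDEL)
        _, biallelic = second_hit("PTEN", cna)
        assert biallelic

    def test_hetloss_plus_focal_intragenic_deletion_is_biallelic(self):
        hit, biallelic = second_hit(
            "PTEN",
            self.hetloss(),
            focal_events=[GenomicInterval("10", 89_020_000, 89_040_000)],
            gene_interval=self.PTEN,
        )
        assert biallelic and hit is SecondHit.FOCAL_INTRAGENIC_DELETION

    def test_hetloss_plus_truncating_variant_is_biallelic(self):
        hit, biallelic = second_hit("PTEN", self.hetloss(), variants=[_variant()])
        assert biallelic and hit is SecondHit.MUTATION

    def test_hetloss_inside_loh_run_is_biallelic(self):
        hit, biallelic = second_hit(
            "PTEN",
            self.hetloss(),
            loh_runs=[GenomicInterval("10", 80_000_000, 95_000_000)],
            gene_interval=self.PTEN,
        )
        assert biallelic and hit is SecondHit.LOH

    def test_lone_hetloss_is_not_biallelic(self):
        hit, biallelic = second_hit("PTEN", self.hetloss(), gene_interval=self.PTEN)
        assert not biallelic and hit is SecondHit.NONE

    def test_missense_is_not_a_second_hit(self):
        _, biallelic = second_hit(
            "PTEN", self.hetloss(), variants=[_variant(consequence="missense")]
        )
        assert not biallelic

    def test_rejects_non_loss_calls(self):
        with pytest.raises(ValueError):
            second_hit("G", CNACall("G", 4.0, 2.0, CNACallType.GAIN))
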