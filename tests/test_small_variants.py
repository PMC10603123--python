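"""VCF intake, VICC scoring, TMB, and the mosaicism flag."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtb_interpret import fixtures as fx
from mtb_interpret.core_io import GenomicInterval
from mtb_interpret.small_variants import (
    DEFAULT_VICC_WEIGHTS,
    CriterionEvidence,
    MosaicismFlag,
    Oncogenicity,
    SmallVariant,
    VariantType,
    classify_score,
    mosaicism_flag,
    read_vcf,
    tmb,
    vicc_score,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">\n'
    '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    "##contig=<ID=1,length=200000000>\n"
)


class TestReadVCF:
    def test_af_computed_from_ad(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            + "1\t100\t.\tA\tT\t.\tPASS\tGENE=KIT;CSQ=missense\tAD\t20,80\n"
        )
        (var,) = read_vcf(p)
        assert var.dna_af == pytest.approx(0.8)
        assert var.gene == "KIT"
        assert var.consequence == "missense"
        assert var.variant_type is VariantType.SNV

    def test_multiallelic_row_yields_two_records(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            + "1\t100\t.\tA\tT,C\t.\tPASS\tGENE=KIT;CSQ=missense\tAD\t10,60,30\n"
        )
        vars_ = read_vcf(p)
        assert len(vars_) == 2
        assert vars_[0].alt == "T" and vars_[0].dna_af == pytest.approx(0.6)
        assert vars_[1].alt == "C" and vars_[1].dna_af == pytest.approx(0.3)

    def test_matched_control_af_captured(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tCONTROL\n"
            + "1\t100\t.\tA\tAT\t.\tPASS\tGENE=RB1;CSQ=frameshift\tAD\t20,80\t94,6\n"
        )
        (var,) = read_vcf(p)
        assert var.control_af == pytest.approx(0.06)
        assert var.variant_type is VariantType.INS

    def test_fixture_vcf_count_matches_generator(self, tmp_path):
        fixture = fx.gen_snvs(fx.FixtureSpec(seed=3, n_snvs=200))
        path = fixture.write_vcf(tmp_path / "fixture.vcf")
        assert len(read_vcf(path)) == len(fixture.variants) == 200


class TestViccScore:
    def test_worked_example_scores_seven_likely_oncogenic(self):
        """Moderate criteria OM1+OM2 with supporting OP2+OP3+OP4 -> 7 points."""
        result = vicc_score(
            [CriterionEvidence(c) for c in ("OM1", "OM2", "OP2", "OP3", "OP4")]
        )
        assert result.score == 7
        assert result.classification is Oncogenicity.LIKELY_ONCOGENIC

    def test_no_criteria_is_vus(self):
        result = vicc_score([])
        assert result.score == 0
        assert result.classification is Oncogenicity.VUS

    def test_very_strong_plus_strong_is_oncogenic(self):
        result = vicc_score([CriterionEvidence("OVS1"), CriterionEvidence("OS1")])
        assert result.score == 12
        assert result.classification is Oncogenicity.ONCOGENIC

    def test_benign_evidence_subtracts(self):
        result = vicc_score([CriterionEvidence("SBVS1"), CriterionEvidence("OP1")])
        assert result.score == -7
        assert result.classification is Oncogenicity.BENIGN

    def test_unmet_criterion_contributes_nothing(self):
        result = vicc_score([CriterionEvidence("OVS1", met=False)])
        assert result.score == 0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            CriterionEvidence("OM9")

    def test_duplicate_code_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            vicc_score([CriterionEvidence("OM1"), CriterionEvidence("OM1")])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        split=st.integers(0, len(DEFAULT_VICC_WEIGHTS)),
        codes=st.permutations(sorted(DEFAULT_VICC_WEIGHTS)),
    )
    def test_additive_over_disjoint_criterion_sets(self, split, codes):
        a = [CriterionEvidence(c) for c in codes[:split]]
        b = [CriterionEvidence(c) for c in codes[split:]]
        assert (
            vicc_score(a).score + vicc_score(b).score == vicc_score(a + b).score
        )

    def test_classification_monotone_in_score(self):
        order = [
            Oncogenicity.BENIGN,
            Oncogenicity.LIKELY_BENIGN,
            Oncogenicity.VUS,
            Oncogenicity.LIKELY_ONCOGENIC,
            Oncogenicity.ONCOGENIC,
        ]
        ranks = [order.index(classify_score(s)) for s in range(-10, 15)]
        assert ranks == sorted(ranks)


def _variants(n_missense, n_synonymous=0, n_indel=0):
    out = []
    pos = 1000
    for consequence, count, typ, ref, alt in (
        ("missense", n_missense, VariantType.SNV, "A", "T"),
        ("synonymous", n_synonymous, VariantType.SNV, "A", "G"),
        ("frameshift", n_indel, VariantType.DEL, "AT", "A"),
    ):
        for _ in range(count):
            out.append(
                SmallVariant(
                    gene="G",
                    hgvs_p="",
                    interval=GenomicInterval("1", pos, pos + len(ref) - 1),
                    ref=ref,
                    alt=alt,
                    variant_type=typ,
                    consequence=consequence,
                    dna_af=0.5,
                )
            )
            pos += 10
    return out


class TestTMB:
    def test_23_variants_over_38_mbp_is_0_6(self):
        result = tmb(_variants(23))
        assert round(result.per_mbp, 1) == 0.6

    def test_no_variants_is_zero(self):
        result = tmb([])
        assert result.per_mbp == 0.0

    def test_76_variants_over_38_mbp_is_2(self):
        assert tmb(_variants(76)).per_mbp == pytest.approx(2.0)

    def test_synonymous_excluded_by_default_included_on_request(self):
        variants = _variants(10, n_synonymous=5)
        assert tmb(variants).qualifying == 10
        assert tmb(variants, nonsynonymous_only=False).qualifying == 15

    def test_snv_and_indel_counts_reported(self):
        result = tmb(_variants(3, n_indel=2))
        assert (result.snv_count, result.indel_count) == (3, 2)

    def test_linear_in_count_inverse_in_footprint(self):
        v = _variants(30)
        assert tmb(v, 38.0).per_mbp == pytest.approx(2 * tmb(v[:15], 38.0).per_mbp)
        assert tmb(v, 19.0).per_mbp == pytest.approx(2 * tmb(v, 38.0).per_mbp)

    def test_nonpositive_footprint_rejected(self):
        with pytest.raises(ValueError):
            tmb(_variants(1), 0.0)


class TestMosaicism:
    def make(self, control_af):
        return SmallVariant(
            gene="RB1",
            hgvs_p="p.F839fs*10",
            interval=GenomicInterval("13", 48_000_000, 48_000_001),
            ref="CT",
            alt="C",
            variant_type=VariantType.DEL,
            consequence="frameshift",
            dna_af=0.81,
            control_af=control_af,
        )

    def test_low_level_control_af_flags_possible_mosaic(self):
        assert mosaicism_flag(self.make(0.057)) is MosaicismFlag.POSSIBLE_MOSAIC

    def test_absent_from_control(self):
        assert mosaicism_flag(self.make(0.0)) is MosaicismFlag.ABSENT

    def test_half_is_germline_het_range(self):
        assert mosaicism_flag(self.make(0.50)) is MosaicismFlag.GERMLINE_HET_RANGE

    def test_band_boundaries(self):
        assert mosaicism_flag(self.make(0.019)) is MosaicismFlag.ABSENT
        assert mosaicism_flag(self.make(0.02)) is MosaicismFlag.POSSIBLE_MOSAIC
        assert mosaicism_flag(self.make(0.30)) is MosaicismFlag.GERMLINE_HET_RANGE

    def test_missing_control_not_assessable(self):
        with pytest.raises(ValueError, match="not assessable"):
            mosaicism_flag(self.make(None))
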