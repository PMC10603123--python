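"""Evidence-level assignment, level ordering, baskets, and ranking."""

import itertools

import pytest

from mtb_interpret.evidence_engine import (
    ALL_LEVELS,
    Basket,
    BiomarkerKind,
    BiomarkerObservation,
    EvidenceLevel,
    KnowledgeEntry,
    Polarity,
    Recommendation,
    SourceLayer,
    StudyType,
    Suffix,
    Tier,
    assign_basket,
    assign_level,
    level_order,
    match_observations,
    rank_recommendations,
    read_knowledge_table,
)


def entry(study_type, entity="GIST", **kw):
    defaults = dict(
        kind=BiomarkerKind.SMALL_VARIANT,
        gene="KIT",
        entity=entity,
        drug="imatinib",
        study_type=study_type,
    )
    defaults.update(kw)
    return KnowledgeEntry(**defaults)


class TestAssignLevel:
    def test_prospective_same_entity_is_m1a(self):
        level = assign_level(entry(StudyType.PROSPECTIVE_OR_META), "GIST")
        assert str(level) == "m1a"

    def test_prospective_other_entity_is_m2a(self):
        level = assign_level(entry(StudyType.PROSPECTIVE_OR_META), "melanoma")
        assert str(level) == "m2a"

    def test_preclinical_is_m3_for_any_entity(self):
        for patient in ("GIST", "melanoma"):
            assert str(assign_level(entry(StudyType.PRECLINICAL), patient)) == "m3"

    def test_rationale_is_m4(self):
        assert str(assign_level(entry(StudyType.RATIONALE), "GIST")) == "m4"

    def test_retrospective_and_case_suffixes(self):
        assert str(assign_level(entry(StudyType.RETROSPECTIVE), "GIST")) == "m1b"
        assert str(assign_level(entry(StudyType.CASE), "GIST")) == "m1c"

    def test_entity_match_normalizes_case_and_spacing(self):
        level = assign_level(entry(StudyType.CASE, entity="  Synovial   Sarcoma"),
                             "synovial sarcoma")
        assert str(level) == "m1c"

    def test_alias_table_maps_entities(self):
        level = assign_level(
            entry(StudyType.CASE, entity="GIST"),
            "gastrointestinal stromal tumor",
            aliases={"gastrointestinal stromal tumor": "gist"},
        )
        assert str(level) == "m1c"

    def test_wildcard_entity_matches_any(self):
        assert str(assign_level(entry(StudyType.CASE, entity="*"), "anything")) == "m1c"

    def test_clinical_tiers_always_suffixed_preclinical_never(self):
        for study, patient in itertools.product(StudyType, ("GIST", "other")):
            level = assign_level(entry(study), patient)
            if level.tier in (Tier.m1, Tier.m2):
                assert level.suffix is not Suffix.none
            else:
                assert level.suffix is Suffix.none


class TestLevelOrder:
    def test_sorts_strongest_first(self):
        levels = [EvidenceLevel.parse(t) for t in ("m3", "m1a", "m2a")]
        assert [str(x) for x in level_order(levels)] == ["m1a", "m2a", "m3"]

    def test_singleton(self):
        assert [str(x) for x in level_order([EvidenceLevel.parse("m4")])] == ["m4"]

    def test_shuffled_full_set_reaches_canonical_order(self):
        shuffled = list(ALL_LEVELS[::-1])
        ordered = level_order(shuffled)
        assert [str(x) for x in ordered] == [
            "m1a", "m1b", "m1c", "m2a", "m2b", "m2c", "m3", "m4"
        ]
        assert level_order(ordered) == ordered  # idempotent

    def test_strict_total_order_axioms(self):
        keys = {lv: lv.sort_key for lv in ALL_LEVELS}
        for a, b in itertools.combinations(ALL_LEVELS, 2):
            assert keys[a] != keys[b]  # antisymmetry: no distinct ties
        for a, b, c in itertools.permutations(ALL_LEVELS, 3):
            if keys[a] < keys[b] and keys[b] < keys[c]:
                assert keys[a] < keys[c]  # transitivity

    def test_suffix_constraints_enforced(self):
        with pytest.raises(ValueError):
            EvidenceLevel(Tier.m1, Suffix.none)
        with pytest.raises(ValueError):
            EvidenceLevel(Tier.m3, Suffix.a)


def obs(kind=BiomarkerKind.SMALL_VARIANT, name="KIT", detail="", layer=SourceLayer.DNA):
    return BiomarkerObservation(kind=kind, gene_or_name=name, detail=detail,
                                source_layer=layer)


class TestAssignBasket:
    def test_kit_variant_is_tyrosine_kinase(self):
        assert assign_basket(obs()) is Basket.TYROSINE_KINASES

    def test_pten_biallelic_loss_is_pi3k_axis(self):
        o = obs(BiomarkerKind.DELETION_BIALLELIC, "PTEN")
        assert assign_basket(o) is Basket.PI3K_AKT_MTOR

    def test_high_tmb_is_immune_evasion(self):
        assert assign_basket(obs(BiomarkerKind.TMB_HIGH, "TMB")) is Basket.IMMUNE_EVASION

    def test_hrd_scar_and_sbs3_are_dna_damage_repair(self):
        assert assign_basket(obs(BiomarkerKind.SCAR_HRD, "HRD")) is Basket.DNA_DAMAGE_REPAIR
        assert assign_basket(obs(BiomarkerKind.SIGNATURE, "SBS3")) is Basket.DNA_DAMAGE_REPAIR

    def test_unmapped_gene_is_unassigned(self):
        assert assign_basket(obs(name="NOVELGENE")) is Basket.UNASSIGNED

    def test_custom_map_overrides(self):
        custom = {"NOVELGENE": Basket.CELL_CYCLE}
        assert assign_basket(obs(name="NOVELGENE"), custom) is Basket.CELL_CYCLE


def rec(drug, level, is_trial=False, layers=(SourceLayer.DNA,)):
    return Recommendation(
        drug=drug,
        biomarkers=tuple(obs(layer=ly) for ly in layers),
        level=EvidenceLevel.parse(level),
        basket=Basket.TYROSINE_KINASES,
        is_trial=is_trial,
        trial_id="NCT000" if is_trial else None,
    )


class TestRanking:
    def test_higher_level_off_label_beats_lower_level_trial(self):
        ranked = rank_recommendations([rec("trial-drug", "m2a", True),
                                       rec("off-label", "m1b")])
        assert [r.drug for r in ranked] == ["off-label", "trial-drug"]

    def test_trial_preferred_at_equal_level(self):
        ranked = rank_recommendations([rec("off-label", "m2a"),
                                       rec("trial-drug", "m2a", True)])
        assert [r.drug for r in ranked] == ["trial-drug", "off-label"]

    def test_dual_layer_breaks_remaining_ties(self):
        ranked = rank_recommendations([
            rec("dna-only", "m2a"),
            rec("dna-rna", "m2a", layers=(SourceLayer.DNA, SourceLayer.RNA)),
        ])
        assert [r.drug for r in ranked] == ["dna-rna", "dna-only"]

    def test_stable_for_identical_keys(self):
        ranked = rank_recommendations([rec("first", "m3"), rec("second", "m3")])
        assert [r.drug for r in ranked] == ["first", "second"]

    def test_output_is_permutation_with_dense_ranks(self):
        recs = [rec(f"d{i}", lvl) for i, lvl in
                enumerate(["m4", "m1a", "m2c", "m3", "m1c"])]
        ranked = rank_recommendations(recs)
        assert sorted(r.drug for r in ranked) == sorted(r.drug for r in recs)
        assert [r.rank for r in ranked] == list(range(1, len(recs) + 1))

    def test_prefer_trials_flag_off(self):
        ranked = rank_recommendations(
            [rec("off-label", "m2a"), rec("trial-drug", "m2a", True)],
            prefer_trials=False,
        )
        assert [r.drug for r in ranked] == ["off-label", "trial-drug"]


class TestMatching:
    def test_resistance_entries_never_become_recommendations(self):
        knowledge = [
            entry(StudyType.PROSPECTIVE_OR_META),
            entry(StudyType.PROSPECTIVE_OR_META, drug="some-inhibitor",
                  polarity=Polarity.RESISTANCE),
        ]
        recs, resistance = match_observations([obs()], knowledge, "GIST")
        assert [r.drug for r in recs] == ["imatinib"]
        assert [e.drug for e in resistance] == ["some-inhibitor"]

    def test_same_drug_entries_pool_to_best_level_with_range(self):
        knowledge = [
            entry(StudyType.PRECLINICAL),
            entry(StudyType.PROSPECTIVE_OR_META),
        ]
        (r,), _ = match_observations([obs()], knowledge, "GIST")
        assert str(r.level) == "m1a"
        assert r.level_range is not None
        assert (str(r.level_range[0]), str(r.level_range[1])) == ("m1a", "m3")

    def test_unmatched_observation_yields_nothing(self):
        recs, _ = match_observations(
            [obs(name="UNRELATED")], [entry(StudyType.CASE)], "GIST"
        )
        assert recs == []

    def test_detail_matcher_filters(self):
        e = entry(StudyType.CASE, detail_matcher="exon 11")
        assert e.matches(obs(detail="KIT exon 11 insertion"))
        assert not e.matches(obs(detail="exon 17 missense"))


def test_knowledge_table_roundtrip(tmp_path):
    p = tmp_path / "kb.tsv"
    p.write_text(
        "kind\tgene\tentity\tdrug\tdrug_class\tstudy_type\ttrial_id\treferences\tpolarity\n"
        "SMALL_VARIANT\tKIT\tGIST\timatinib\tTKI\tPROSPECTIVE_OR_META\t\tPMID:1;PMID:2\tRESPONSE\n"
        "AMPLIFICATION\tCDK4\t*\tpalbociclib\tCDK4/6i\tPRECLINICAL\tNCT123\t\tRESPONSE\n"
    )
    entries = read_knowledge_table(p)
    assert len(entries) == 2
    assert entries[0].references == ("PMID:1", "PMID:2")
    assert entries[1].trial_id == "NCT123"
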