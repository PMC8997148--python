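"""Medal assignment rules, somatic refinement, and triage flags."""

import random

import pytest

from varmedal import (
    Consequence,
    Medal,
    PliTier,
    SomaticCategory,
    classify_calls,
    classify_germline,
    flag_cterm_caution,
    pli_tier,
    refine_silver,
    somatic_category,
)
from varmedal.classifier import MedalCall

from conftest import make_bundle, make_record, pathogenic, vus


class TestClassifyGermline:
    def test_truncating_tsg_with_two_star_assertion_is_gold(self):
        bundle = make_bundle(kind=Consequence.FRAMESHIFT, tsg=True, assertions=(pathogenic(stars=2),))
        medal, reasons = classify_germline(bundle)
        assert medal is Medal.GOLD
        assert "truncating:frameshift" in reasons and "starred_assertion" in reasons

    def test_specialty_source_substitutes_for_stars(self):
        bundle = make_bundle(kind=Consequence.MISSENSE, assertions=(pathogenic(source="iarc_tp53"),))
        assert classify_germline(bundle)[0] is Medal.GOLD

    def test_inframe_deletion_non_tsg_with_locus_db_is_silver(self):
        bundle = make_bundle(kind=Consequence.INFRAME_INDEL, tsg=False, assertions=(vus(),))
        medal, reasons = classify_germline(bundle)
        assert medal is Medal.SILVER
        assert "inframe_indel" in reasons

    def test_truncation_in_non_tsg_gene_is_silver(self):
        bundle = make_bundle(kind=Consequence.NONSENSE, tsg=False, lof=False, assertions=(vus(),))
        assert classify_germline(bundle)[0] is Medal.SILVER

    def test_tolerated_missense_without_assertions_is_bronze(self):
        bundle = make_bundle(kind=Consequence.MISSENSE, tolerated=True)
        assert classify_germline(bundle)[0] is Medal.BRONZE

    def test_synonymous_without_evidence_is_unknown(self):
        bundle = make_bundle(kind=Consequence.SYNONYMOUS)
        medal, reasons = classify_germline(bundle)
        assert medal is Medal.UNKNOWN and reasons == ()

    def test_one_star_clinvar_only_is_not_gold(self):
        bundle = make_bundle(kind=Consequence.FRAMESHIFT, tsg=True, assertions=(pathogenic(stars=1),))
        assert classify_germline(bundle)[0] is not Medal.GOLD

    def test_truncating_in_non_disease_gene_is_not_gold(self):
        bundle = make_bundle(kind=Consequence.FRAMESHIFT, tsg=False, lof=False,
                             assertions=(pathogenic(stars=2),))
        assert classify_germline(bundle)[0] is not Medal.GOLD

    def test_assertion_order_does_not_matter(self):
        assertions = [pathogenic(stars=2), vus(), pathogenic(source="bic"), vus(source="umd")]
        rng = random.Random(7)
        outcomes = set()
        for _ in range(10):
            rng.shuffle(assertions)
            outcomes.add(classify_germline(make_bundle(assertions=tuple(assertions))))
        assert len(outcomes) == 1

    def test_adding_strong_assertion_never_lowers_medal(self):
        rank = {Medal.UNKNOWN: 0, Medal.BRONZE: 1, Medal.SILVER: 2, Medal.GOLD: 3}
        for kind in Consequence:
            for tsg in (False, True):
                base = make_bundle(kind=kind, tsg=tsg, lof=tsg, assertions=(vus(),))
                boosted = make_bundle(kind=kind, tsg=tsg, lof=tsg,
                                      assertions=(vus(), pathogenic(stars=2)))
                assert rank[classify_germline(boosted)[0]] >= rank[classify_germline(base)[0]]

    def test_removing_all_evidence_never_raises_medal(self):
        bare = make_bundle(kind=Consequence.FRAMESHIFT, tsg=True, assertions=())
        assert classify_germline(bare)[0] in (Medal.UNKNOWN, Medal.BRONZE)


class TestSomaticAndRefinement:
    def test_somatic_category_passthrough(self):
        assert somatic_category(make_bundle(somatic=SomaticCategory.GOLD)) is SomaticCategory.GOLD
        assert somatic_category(make_bundle()) is SomaticCategory.NONE

    def _call(self, medal, som):
        bundle = make_bundle(somatic=som)
        return MedalCall(
            record=make_record(), bundle=bundle, germline_medal=medal,
            somatic_category=som, reasons=("x",) if medal is not Medal.UNKNOWN else (),
            caution_cterm=False, pli_tier=PliTier.ABSENT,
        )

    @pytest.mark.parametrize(
        ("medal", "som", "retained"),
        [
            (Medal.SILVER, SomaticCategory.GOLD, True),
            (Medal.SILVER, SomaticCategory.SILVER, True),
            (Medal.SILVER, SomaticCategory.NONE, False),
            (Medal.GOLD, SomaticCategory.NONE, True),
            (Medal.BRONZE, SomaticCategory.GOLD, None),
            (Medal.UNKNOWN, SomaticCategory.NONE, None),
        ],
    )
    def test_refinement_scope(self, medal, som, retained):
        (out,) = refine_silver([self._call(medal, som)])
        assert out.retained_after_refinement is retained

    def test_gold_and_retained_silver_disjoint(self):
        # one medal per classified record: a variant-patient pair cannot be
        # both Gold and retained-Silver in a single classification pass
        gold_bundle = make_bundle(assertions=(pathogenic(stars=2),))
        silver_bundle = make_bundle(kind=Consequence.INFRAME_INDEL, tsg=False,
                                    assertions=(vus(),), somatic=SomaticCategory.GOLD)
        from varmedal import classify_calls
        calls = classify_calls([
            (make_record(patient="P1"), gold_bundle),
            (make_record(patient="P2", pos=2000), silver_bundle),
        ])
        gold = {(c.key, c.patient_id) for c in calls if c.germline_medal is Medal.GOLD}
        silver = {
            (c.key, c.patient_id)
            for c in calls
            if c.germline_medal is Medal.SILVER and c.retained_after_refinement
        }
        assert gold.isdisjoint(silver)


class TestCtermCaution:
    def test_stop_at_last_residue_flagged(self, gold_table_by_gene):
        (cux1,) = gold_table_by_gene["CUX1"]
        assert flag_cterm_caution(make_bundle(
            kind=cux1.consequence.kind, aa_position=678, protein_size=678))

    def test_msh6_near_terminal_flagged(self):
        assert flag_cterm_caution(make_bundle(
            kind=Consequence.SPLICE, aa_position=1334, protein_size=1360))

    def test_mid_protein_splice_not_flagged(self):
        # fraction 1892/3056 ~ 0.62
        assert not flag_cterm_caution(make_bundle(
            kind=Consequence.SPLICE, aa_position=1892, protein_size=3056))

    def test_final_exon_flag_overrides_fraction(self):
        # N-terminal truncation (19% of the protein) in a final-exon gene
        assert flag_cterm_caution(make_bundle(
            kind=Consequence.NONSENSE, aa_position=788, protein_size=4061, in_final_exon=True))

    def test_boundary_fraction_rounds_half_up(self):
        # 2424/2696 = 0.89910... rounds to 0.90 at two decimals -> flagged
        assert flag_cterm_caution(make_bundle(
            kind=Consequence.FRAMESHIFT, aa_position=2424, protein_size=2696))

    def test_missense_never_flagged(self):
        assert not flag_cterm_caution(make_bundle(
            kind=Consequence.MISSENSE, aa_position=999, protein_size=1000))

    def test_caution_genes_from_curated_table(self, gold_table):
        flagged = set()
        for row in gold_table:
            bundle = make_bundle(
                kind=row.consequence.kind,
                aa_position=row.consequence.aa_position,
                protein_size=row.gene.protein_size,
                in_final_exon=row.consequence.in_final_exon,
            )
            if flag_cterm_caution(bundle):
                flagged.add(row.gene_symbol)
        # The fraction rule recovers every curated caution gene.  BRCA2
        # (V3079fs at 90.1%) and POLQ (splice at 92.1%) are the two extra
        # hits: no monotone threshold can admit NSD1's flagged 89.9%
        # truncation while excluding them.
        caution_genes = {"CUX1", "FLCN", "FLG", "MSH6", "NSD1", "PRDM9", "USP6"}
        assert caution_genes <= flagged
        assert flagged - caution_genes == {"BRCA2", "POLQ"}


class TestPliTier:
    @pytest.mark.parametrize(
        ("pli", "tier"),
        [
            (1.0, PliTier.HIGH),
            (0.9, PliTier.HIGH),
            (0.79, PliTier.INTERMEDIATE),
            (0.5, PliTier.INTERMEDIATE),
            (0.0, PliTier.LOW),
            (None, PliTier.ABSENT),
        ],
    )
    def test_tiers(self, pli, tier):
        assert pli_tier(pli) is tier

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pli_tier(1.2)


def test_classify_calls_assembles_full_medal_call():
    rec = make_record()
    bundle = make_bundle(pli=0.95, assertions=(pathogenic(),))
    (call,) = classify_calls([(rec, bundle)])
    assert call.germline_medal is Medal.GOLD
    assert call.pli_tier is PliTier.HIGH
    assert call.retained_after_refinement is True
    assert call.reasons
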