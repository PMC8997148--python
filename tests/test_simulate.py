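"""Synthetic-cohort generator: determinism, plantedness, end-to-end recovery."""

import hashlib
import logging
from pathlib import Path

import numpy as np
import pytest

from varmedal import (
    FlagKind,
    Medal,
    SimConfig,
    apply_caller_filters,
    apply_post_filters,
    build_matrix,
    detect_common_variants,
    detect_mapping_artifacts,
    read_cohort_vcf,
    read_evidence_dir,
    run_pipeline,
    simulate_cohort,
    write_cohort,
)

SMALL = SimConfig(
    seed=2, n_patients=30, n_gold_like=12, n_silver_like=15, n_bronze_like=8,
    n_lowqual=10, n_offpanel=5,
)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SMALL)


def _dir_digest(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(d.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(d)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()


class TestDeterminism:
    def test_same_seed_same_records(self, small_cohort):
        again = simulate_cohort(SMALL)
        assert again.records == small_cohort.records
        assert again.truth.variant_class == small_cohort.truth.variant_class

    def test_same_seed_identical_files(self, small_cohort, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        write_cohort(small_cohort, a)
        write_cohort(simulate_cohort(SMALL), b)
        assert _dir_digest(a) == _dir_digest(b)

    def test_different_seed_differs(self, small_cohort):
        other = simulate_cohort(
            SimConfig(**{**SMALL.__dict__, "seed": 3})
        )
        assert other.records != small_cohort.records


class TestPlantedStructure:
    def test_planted_gold_passes_both_filter_stages(self, small_cohort):
        gold_recs = [
            r for r in small_cohort.records
            if small_cohort.truth.variant_class.get(r.key) == "gold"
        ]
        passed, _ = apply_caller_filters(gold_recs, small_cohort.tables.popfreq)
        assert len(passed) == len(gold_recs)
        assert len(apply_post_filters(passed)) == len(gold_recs)

    def test_common_position_carried_by_every_patient(self, small_cohort):
        common = [k for k, v in small_cohort.truth.variant_class.items() if v == "common"]
        matrix = build_matrix(small_cohort.records, patients=small_cohort.patient_ids)
        for key in common:
            assert len(matrix.carriers(key.position)) == SMALL.n_patients

    def test_artifact_positions_have_varied_alts_and_deficit(self, small_cohort):
        artifact_pos = {
            k.position
            for k, v in small_cohort.truth.variant_class.items()
            if v == "artifact"
        }
        assert len(artifact_pos) == SMALL.n_artifact_positions
        matrix = build_matrix(small_cohort.records, patients=small_cohort.patient_ids)
        flagged = {
            (f.chrom, f.pos)
            for f in detect_mapping_artifacts(matrix)
            if f.flag is FlagKind.MAPPING_ARTIFACT
        }
        assert artifact_pos <= flagged

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SimConfig(panel_list_sizes=(30, 30), panel_overlap=20, n_gold_like=100)

    def test_generated_vcfs_reread_cleanly(self, small_cohort, tmp_path, caplog):
        out = write_cohort(small_cohort, tmp_path / "c")
        with caplog.at_level(logging.WARNING, logger="varmedal"):
            records = read_cohort_vcf(sorted((out / "vcf").glob("*.vcf")))
        assert caplog.records == []
        assert sorted(records, key=repr) == sorted(small_cohort.records, key=repr)
        tables = read_evidence_dir(out / "evidence")
        assert tables.gene_by_key == small_cohort.tables.gene_by_key
        assert tables.assertions == small_cohort.tables.assertions
        assert tables.popfreq == small_cohort.tables.popfreq


class TestEndToEnd:
    def test_pipeline_recovers_planted_gold_exactly(self, small_cohort):
        res = run_pipeline(
            small_cohort.records, small_cohort.tables, small_cohort.panel,
            small_cohort.patient_ids,
        )
        got = {c.key for c in res.gold_retained}
        want = small_cohort.truth.gold_keys
        assert got == want  # precision = recall = 1 under unambiguous evidence

    def test_gold_carriers_match_truth(self, small_cohort):
        res = run_pipeline(
            small_cohort.records, small_cohort.tables, small_cohort.panel,
            small_cohort.patient_ids,
        )
        got = {c.patient_id for c in res.gold_retained}
        want = {p for p, c in small_cohort.truth.patient_carrier.items() if c}
        assert got == want

    def test_curation_trims_candidates_to_planted_gold(self, small_cohort):
        res = run_pipeline(
            small_cohort.records, small_cohort.tables, small_cohort.panel,
            small_cohort.patient_ids,
        )
        n_artifact_records = sum(
            1 for c in res.calls
            if small_cohort.truth.variant_class.get(c.key) == "artifact"
        )
        assert res.funnel["gold_candidates"] > res.funnel["gold_after_curation"]
        assert res.funnel["gold_after_curation"] == SMALL.n_gold_like
        assert n_artifact_records > 0

    def test_ambiguous_evidence_degrades_gold_to_lower_tier(self, small_cohort):
        stripped = simulate_cohort(SMALL)
        stripped.tables.assertions = {}  # remove all database support
        res = run_pipeline(
            stripped.records, stripped.tables, stripped.panel, stripped.patient_ids,
        )
        gold_keys = stripped.truth.gold_keys
        medals = {
            c.germline_medal for c in res.calls if c.key in gold_keys
        }
        assert Medal.GOLD not in medals
        assert medals <= {Medal.SILVER, Medal.UNKNOWN}


class TestDetectorOperatingCharacteristics:
    def test_artifact_sensitivity_and_false_flag_rate(self):
        """>= 95% of planted artifact positions flagged, <= 1% of clean ones."""
        hits = total_artifacts = false_flags = clean_total = 0
        for seed in range(25):
            cfg = SimConfig(**{**SMALL.__dict__, "seed": 100 + seed})
            cohort = simulate_cohort(cfg)
            matrix = build_matrix(cohort.records, patients=cohort.patient_ids)
            flagged = {
                (f.chrom, f.pos)
                for f in detect_mapping_artifacts(matrix) + detect_common_variants(matrix)
                if f.flag is not FlagKind.CLEAN
            }
            truth_bad = {
                k.position
                for k, v in cohort.truth.variant_class.items()
                if v in ("artifact", "common")
            }
            clean = {k.position for k, v in cohort.truth.variant_class.items()
                     if v not in ("artifact", "common")}
            hits += len(truth_bad & flagged)
            total_artifacts += len(truth_bad)
            false_flags += len(flagged & clean)
            clean_total += len(clean)
        assert hits / total_artifacts >= 0.95
        assert false_flags / clean_total <= 0.01

    def test_covariate_generator_hits_target_odds_ratio(self):
        # marginal check at large n: carrier/non-carrier family-history OR
        cfg = SimConfig(seed=42, n_patients=20000, carrier_effect={"family_history": 3.21})
        from varmedal import simulate_patients
        patients, carrier = simulate_patients(cfg)
        a = sum(1 for p in patients if carrier[p.patient_id] and p.family_history)
        b = sum(1 for p in patients if carrier[p.patient_id] and not p.family_history)
        c = sum(1 for p in patients if not carrier[p.patient_id] and p.family_history)
        d = sum(1 for p in patients if not carrier[p.patient_id] and not p.family_history)
        assert (a * d) / (b * c) == pytest.approx(3.21, rel=0.15)
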