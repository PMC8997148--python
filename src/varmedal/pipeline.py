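"""End-to-end orchestration: filters -> panel -> medals -> curation -> summary.

Each stage logs a funnel line (record counts in and out) to the package
logger, mirroring how cohort variant funnels are reported: raw calls,
post-quality-filter calls, in-panel calls, Gold/Silver candidates, retained
Silver after somatic refinement, and Gold after cohort curation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import EvidenceTables, GenePanel, annotate
from .classifier import ClassifierConfig, Medal, MedalCall, classify_calls
from .cohort import (
    CohortSummary,
    CurationFlag,
    build_matrix,
    curate,
    detect_common_variants,
    detect_mapping_artifacts,
    summarize_cohort,
)
from .filters import FilterConfig, apply_caller_filters, passes_post_filters
from .model_io import VariantRecord

logger = logging.getLogger("varmedal")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    funnel: dict[str, int]
    calls: list[MedalCall]
    gold_retained: list[MedalCall]
    silver_retained: list[MedalCall]
    curation_flags: list[CurationFlag]
    summary: CohortSummary


def run_pipeline(
    records: Sequence[VariantRecord],
    tables: EvidenceTables,
    panel: GenePanel,
    patient_ids: Sequence[str],
    filter_config: FilterConfig = FilterConfig(),
    classifier_config: ClassifierConfig = ClassifierConfig(),
    artifact_min_patients: int = 3,
    common_fraction_threshold: float = 1.0,
) -> PipelineResult:
    """Run the full prioritization pipeline over a cohort of records.

    ``patient_ids`` fixes the cohort roster; carrier fractions (and the
    common-variant rule) are computed against it, not against the patients
    that happen to appear in the surviving calls.
    """
    funnel: dict[str, int] = {"raw": len(records)}

    passed, excluded = apply_caller_filters(records, tables.popfreq, filter_config)
    funnel["after_caller_filters"] = len(passed)
    logger.info("caller filters: %d -> %d (%d excluded)", len(records), len(passed), len(excluded))

    annotated = annotate(passed, panel, tables)
    funnel["in_panel"] = len(annotated)
    logger.info("panel restriction: %d -> %d", len(passed), len(annotated))

    calls = classify_calls(annotated, classifier_config)
    supported = [c for c in calls if passes_post_filters(c.record, filter_config)]
    gold = [c for c in supported if c.germline_medal is Medal.GOLD]
    silver = [c for c in supported if c.germline_medal is Medal.SILVER]
    silver_retained = [c for c in silver if c.retained_after_refinement]
    funnel["gold_candidates"] = len(gold)
    funnel["silver_candidates"] = len(silver)
    funnel["silver_retained"] = len(silver_retained)
    logger.info(
        "classification: %d gold, %d silver (%d retained after somatic refinement)",
        len(gold), len(silver), len(silver_retained),
    )

    matrix = build_matrix([c.record for c in gold], patients=patient_ids)
    flags = detect_mapping_artifacts(matrix, min_patients=artifact_min_patients)
    flags += detect_common_variants(matrix, fraction_threshold=common_fraction_threshold)
    gold_retained, removed = curate(gold, flags)
    funnel["gold_after_curation"] = len(gold_retained)
    for call, flag in removed:
        logger.info("curation removed %s (%s): %s", call.key, flag.flag.value, flag.rationale)

    summary = summarize_cohort(gold_retained, n_patients=len(patient_ids))
    return PipelineResult(
        funnel=funnel,
        calls=calls,
        gold_retained=gold_retained,
        silver_retained=silver_retained,
        curation_flags=[f for f in flags],
        summary=summary,
    )
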