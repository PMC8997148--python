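"""Caller-level exclusion rules and post-classification read-support filters.

Two sequential stages act on read support:

* **Caller filters** remove sites with total depth < 10, heterozygous allele
  balance (ABHet = ref/(ref+alt)) outside [0.2, 0.8], population popmax
  allele frequency >= 0.01, fewer than 10 alternate reads, or a heterozygous
  minor allelic fraction below 0.25.
* **Post filters** (applied after classification) keep only calls with at
  least 20 total reads and VAF >= 0.25.

Boundary semantics follow a literal reading of each comparator: exactly 10
total reads passes, ABHet exactly 0.2 or 0.8 passes, popmax strictly below
0.01 passes, exactly 20 total reads and VAF exactly 0.25 pass.  Records
without depths cannot be depth-filtered; they are excluded with an explicit
``missing_depth`` reason rather than failing the run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .model_io import (
    Genotype,
    PopulationFrequency,
    UndefinedValueError,
    VariantKey,
    VariantRecord,
)

__all__ = [
    "FilterConfig",
    "ExclusionRecord",
    "vaf",
    "abhet",
    "minor_allelic_fraction",
    "apply_caller_filters",
    "apply_post_filters",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for both filter stages (defaults are the study settings)."""

    min_depth: int = 10
    abhet_low: float = 0.2
    abhet_high: float = 0.8
    max_popmax_af: float = 0.01
    min_alt_reads: int = 10
    min_minor_allelic_fraction: float = 0.25
    min_total_reads_post: int = 20
    min_vaf_post: float = 0.25

    def __post_init__(self) -> None:
        fractions = (
            self.abhet_low, self.abhet_high, self.max_popmax_af,
            self.min_minor_allelic_fraction, self.min_vaf_post,
        )
        if not all(0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("fraction thresholds must be in [0,1]")
        if not self.abhet_low < self.abhet_high:
            raise ValueError("abhet_low must be < abhet_high")
        if min(self.min_depth, self.min_alt_reads, self.min_total_reads_post) < 0:
            raise ValueError("read thresholds must be >= 0")


def vaf(ref_depth: int, alt_depth: int) -> float:
    """Variant allele fraction: alt / (ref + alt)."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise UndefinedValueError("VAF undefined at zero total depth")
    return alt_depth / total


def abhet(ref_depth: int, alt_depth: int) -> float:
    """Heterozygous allele balance: ref / (ref + alt)."""
    total = ref_depth + alt_depth
    if total <= 0:
        raise UndefinedValueError("ABHet undefined at zero total depth")
    return ref_depth / total


def minor_allelic_fraction(ref_depth: int, alt_depth: int) -> float:
    """min(VAF, 1 - VAF) — fraction of the less-supported allele at a het site."""
    v = vaf(ref_depth, alt_depth)
    return min(v, 1.0 - v)


@dataclass(frozen=True)
class ExclusionRecord:
    """One excluded record with the rule(s) that fired, in evaluation order."""

    record: VariantRecord
    reasons: tuple[str, ...]


def _caller_reasons(
    rec: VariantRecord,
    popmax: float,
    config: FilterConfig,
) -> tuple[str, ...]:
    reasons: list[str] = []
    if not rec.has_depths:
        reasons.append("missing_depth")
    else:
        total = rec.total_depth
        if total < config.min_depth:
            reasons.append("min_depth")
        if total > 0 and rec.genotype is Genotype.HET:
            ab = abhet(rec.ref_depth, rec.alt_depth)
            if ab < config.abhet_low or ab > config.abhet_high:
                reasons.append("abhet")
            if minor_allelic_fraction(rec.ref_depth, rec.alt_depth) < config.min_minor_allelic_fraction:
                reasons.append("minor_allelic_fraction")
        if rec.alt_depth < config.min_alt_reads:
            reasons.append("min_alt_reads")
        if total == 0:
            reasons.append("zero_depth")
    if popmax >= config.max_popmax_af:
        reasons.append("popmax_af")
    return tuple(reasons)


def apply_caller_filters(
    records: Iterable[VariantRecord],
    popfreqs: Optional[Mapping[VariantKey, PopulationFrequency]] = None,
    config: FilterConfig = FilterConfig(),
) -> tuple[list[VariantRecord], list[ExclusionRecord]]:
    """Apply the caller-level exclusion rules.

    Returns (passing records, exclusion log).  Population frequencies are
    joined by variant key; a variant absent from the table is treated as never
    observed (popmax 0).  The log partitions the input: passed + excluded
    equals the number of input records.
    """
    popfreqs = popfreqs or {}
    passed: list[VariantRecord] = []
    excluded: list[ExclusionRecord] = []
    for rec in records:
        pf = popfreqs.get(rec.key)
        popmax = pf.popmax_af if pf is not None else 0.0
        reasons = _caller_reasons(rec, popmax, config)
        if reasons:
            excluded.append(ExclusionRecord(record=rec, reasons=reasons))
        else:
            passed.append(rec)
    return passed, excluded


def passes_post_filters(rec: VariantRecord, config: FilterConfig = FilterConfig()) -> bool:
    """Post-classification support check: total >= 20 reads and VAF >= 0.25."""
    if not rec.has_depths or rec.total_depth == 0:
        return False
    return (
        rec.total_depth >= config.min_total_reads_post
        and vaf(rec.ref_depth, rec.alt_depth) >= config.min_vaf_post
    )


def apply_post_filters(
    records: Iterable[VariantRecord],
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Keep records with total depth >= 20 and VAF >= 0.25."""
    return [rec for rec in records if passes_post_filters(rec, config)]
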