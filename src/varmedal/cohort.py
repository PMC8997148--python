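"""Cohort-level curation and per-patient / per-gene / per-type summaries.

Codifies the manual review step of the study design: recurrent positions
where carriers show *varied* alternate alleles, always with fewer alternate
than reference reads, are mapping/sequencing artifacts; a position carried by
the whole cohort is a common (population) variant rather than a rare
pathogenic one.  Both are removed from the final Gold set, and every removal
is logged with its rationale.

Variant identity for deduplicated counts is (chrom, pos, ref, alt), so a
variant recurring in two patients counts once at variant level and twice at
occurrence/carrier level.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Protocol, Sequence

from .model_io import (
    ConsequenceClass,
    Genotype,
    VariantKey,
    VariantRecord,
    chrom_sort_key,
)

__all__ = [
    "CohortMatrix",
    "FlagKind",
    "CurationFlag",
    "build_matrix",
    "detect_mapping_artifacts",
    "detect_common_variants",
    "curate",
    "summarize_cohort",
    "CohortSummary",
]


class CallLike(Protocol):
    """Anything summarizable: a medal call or a curated-table row."""

    @property
    def key(self) -> VariantKey: ...
    @property
    def patient_id(self) -> str: ...
    @property
    def gene_symbol(self) -> str: ...
    @property
    def consequence(self) -> ConsequenceClass: ...


class FlagKind(str, Enum):
    MAPPING_ARTIFACT = "mapping_artifact"
    COMMON_IN_COHORT = "common_in_cohort"
    CLEAN = "clean"


@dataclass(frozen=True)
class CurationFlag:
    """One curation verdict per genomic position (chrom, pos)."""

    chrom: str
    pos: int
    flag: FlagKind
    rationale: str


@dataclass(frozen=True)
class MatrixCell:
    alt: str
    ref_depth: Optional[int]
    alt_depth: Optional[int]
    genotype: Genotype


@dataclass
class CohortMatrix:
    """Patients x positions incidence view with per-cell allele and depths."""

    patients: tuple[str, ...]
    cells: dict[tuple[str, int], dict[str, list[MatrixCell]]] = field(default_factory=dict)

    def carriers(self, position: tuple[str, int]) -> list[str]:
        """Patients carrying any alternate allele at the position."""
        by_patient = self.cells.get(position, {})
        return [
            p
            for p, cs in by_patient.items()
            if any(c.genotype is not Genotype.HOM_REF for c in cs)
        ]

    @property
    def positions(self) -> list[tuple[str, int]]:
        return sorted(self.cells, key=lambda p: (chrom_sort_key(p[0]), p[1]))


def build_matrix(
    records: Iterable[VariantRecord], patients: Optional[Sequence[str]] = None
) -> CohortMatrix:
    """Build the cohort incidence matrix from variant records.

    ``patients`` fixes the cohort roster (and hence carrier fractions); if
    omitted, the roster is the set of patients seen in the records.
    """
    cells: dict[tuple[str, int], dict[str, list[MatrixCell]]] = defaultdict(lambda: defaultdict(list))
    seen: list[str] = []
    for rec in records:
        if rec.patient_id not in seen:
            seen.append(rec.patient_id)
        cells[rec.key.position][rec.patient_id].append(
            MatrixCell(
                alt=rec.key.alt,
                ref_depth=rec.ref_depth,
                alt_depth=rec.alt_depth,
                genotype=rec.genotype,
            )
        )
    roster = tuple(patients) if patients is not None else tuple(sorted(seen))
    return CohortMatrix(patients=roster, cells={k: dict(v) for k, v in cells.items()})


def detect_mapping_artifacts(
    matrix: CohortMatrix, min_patients: int = 3
) -> list[CurationFlag]:
    """Flag positions that look like mapping/sequencing artifacts.

    A position is an artifact when at least ``min_patients`` patients carry
    it, carriers show two or more distinct alternate alleles, and every
    carrier has fewer alternate than reference reads.  Positions evaluated
    but not matching are returned flagged ``clean``.
    """
    flags: list[CurationFlag] = []
    for pos in matrix.positions:
        carriers = matrix.carriers(pos)
        carrier_cells = [
            c
            for p in carriers
            for c in matrix.cells[pos][p]
            if c.genotype is not Genotype.HOM_REF
        ]
        alts = {c.alt for c in carrier_cells}
        alt_deficit = all(
            c.ref_depth is not None
            and c.alt_depth is not None
            and c.alt_depth < c.ref_depth
            for c in carrier_cells
        )
        if len(carriers) >= min_patients and len(alts) >= 2 and carrier_cells and alt_deficit:
            flags.append(
                CurationFlag(
                    chrom=pos[0],
                    pos=pos[1],
                    flag=FlagKind.MAPPING_ARTIFACT,
                    rationale=(
                        f"{len(carriers)} carriers with {len(alts)} distinct alternate "
                        "alleles, all with fewer alternate than reference reads"
                    ),
                )
            )
        else:
            flags.append(CurationFlag(pos[0], pos[1], FlagKind.CLEAN, "no artifact signature"))
    return flags


def detect_common_variants(
    matrix: CohortMatrix, fraction_threshold: float = 1.0
) -> list[CurationFlag]:
    """Flag positions carried by (at least) the given fraction of the cohort.

    The default threshold 1.0 flags only positions present in every patient.
    """
    n = len(matrix.patients)
    flags: list[CurationFlag] = []
    for pos in matrix.positions:
        carriers = matrix.carriers(pos)
        if n > 0 and len(carriers) / n >= fraction_threshold:
            flags.append(
                CurationFlag(
                    chrom=pos[0],
                    pos=pos[1],
                    flag=FlagKind.COMMON_IN_COHORT,
                    rationale=f"carried by {len(carriers)}/{n} patients",
                )
            )
        else:
            flags.append(CurationFlag(pos[0], pos[1], FlagKind.CLEAN, "cohort-rare"))
    return flags


def curate(
    calls: Sequence[CallLike], flags: Iterable[CurationFlag]
) -> tuple[list[CallLike], list[tuple[CallLike, CurationFlag]]]:
    """Remove calls at flagged positions.

    Returns (retained calls, removal log of (call, flag) pairs).  Adding
    flags never increases the retained set.
    """
    flagged: dict[tuple[str, int], CurationFlag] = {
        (f.chrom, f.pos): f for f in flags if f.flag is not FlagKind.CLEAN
    }
    retained: list[CallLike] = []
    removed: list[tuple[CallLike, CurationFlag]] = []
    for call in calls:
        f = flagged.get(call.key.position)
        if f is None:
            retained.append(call)
        else:
            removed.append((call, f))
    return retained, removed


def _percent_half_up(value: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level counts over a final call set."""

    n_patients: int
    occurrences: int
    unique_variants: int
    distinct_genes: int
    carrier_patients: int
    carrier_percent: float
    consequence_counts: dict[str, int]
    gene_occurrences: dict[str, int]
    patients_with_k_calls: dict[int, int]
    carrier_frequency_percent: dict[VariantKey, float]


def summarize_cohort(calls: Sequence[CallLike], n_patients: int) -> CohortSummary:
    """Summarize a final call set against a cohort of ``n_patients``.

    Consequence counts are over unique variants (deduplicated by chrom, pos,
    ref, alt); occurrence, carrier, and per-patient counts keep every call.
    Percentages round half-up: whole percent for the carrier fraction, one
    decimal for per-variant carrier frequencies.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be > 0")

    by_key: dict[VariantKey, CallLike] = {}
    carriers_by_key: dict[VariantKey, set[str]] = defaultdict(set)
    per_patient = Counter()
    genes = set()
    for c in calls:
        by_key.setdefault(c.key, c)
        carriers_by_key[c.key].add(c.patient_id)
        per_patient[c.patient_id] += 1
        genes.add(c.gene_symbol)

    consequence_counts = Counter(c.consequence.kind.value for c in by_key.values())
    k_counts = Counter(per_patient.values())
    carrier_patients = len(per_patient)

    return CohortSummary(
        n_patients=n_patients,
        occurrences=len(calls),
        unique_variants=len(by_key),
        distinct_genes=len(genes),
        carrier_patients=carrier_patients,
        carrier_percent=_percent_half_up(100.0 * carrier_patients / n_patients),
        consequence_counts=dict(consequence_counts),
        gene_occurrences=dict(Counter(c.gene_symbol for c in calls)),
        patients_with_k_calls=dict(sorted(k_counts.items())),
        carrier_frequency_percent={
            k: _percent_half_up(100.0 * len(p) / n_patients, decimals=1)
            for k, p in carriers_by_key.items()
        },
    )
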