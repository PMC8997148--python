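"""Medal-based germline pathogenicity classification.

Four tiers, assigned by precedence (Gold > Silver > Bronze > Unknown):

* **Gold** — the variant is truncating (frameshift, nonsense, splice) or
  carries a pathogenic/likely-pathogenic assertion, the gene is
  disease-associated (loss-of-function disease mechanism or tumor
  suppressor), and the evidence is high-confidence: a star-rated pathogenic
  assertion with >= 2 review stars, or a pathogenic assertion from a
  configured specialty locus database (IARC-TP53, BIC, COSMIC, ...).
* **Silver** — not Gold, the variant is an in-frame indel, a truncation in a
  non-tumor-suppressor gene, or a damaging-predicted missense, and at least
  one configured database asserts it.
* **Bronze** — in-silico algorithms predict the variant tolerated and no
  pathogenic assertion contradicts them.
* **Unknown** — no rule fires.

Classification is a pure function of the evidence bundle: deterministic and
independent of assertion ordering.  Silver calls are afterwards refined
against the somatic catalogue: only Silver variants whose exact change is
catalogued Gold or Silver somatically are retained.

Two triage annotations accompany each call: a C-terminal *caution* flag for
truncations in the last ~10% of the protein (or in the final coding exon,
where nonsense-mediated decay is typically escaped), and a pLI tier
(high >= 0.9, intermediate in [0.5, 0.9), low < 0.5) summarising the gene's
loss-of-function intolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

from .annotation import EvidenceBundle, truncation_protein_fraction
from .model_io import (
    Consequence,
    SomaticCategory,
    VariantRecord,
)

__all__ = [
    "Medal",
    "PliTier",
    "ClassifierConfig",
    "MedalCall",
    "classify_germline",
    "somatic_category",
    "flag_cterm_caution",
    "pli_tier",
    "classify_calls",
    "refine_silver",
]


class Medal(str, Enum):
    GOLD = "gold"
    SILVER = "silver"
    BRONZE = "bronze"
    UNKNOWN = "unknown"


class PliTier(str, Enum):
    HIGH = "high"
    INTERMEDIATE = "intermediate"
    LOW = "low"
    ABSENT = "absent"


#: Specialty locus databases whose pathogenic assertions qualify for Gold.
DEFAULT_SPECIALTY_SOURCES = frozenset(
    {"iarc_tp53", "asu_tert", "arup_ret", "bic", "pcfp", "cosmic"}
)

#: Databases whose assertions qualify a variant for Silver (any match counts).
DEFAULT_SILVER_SOURCES = DEFAULT_SPECIALTY_SOURCES | frozenset(
    {"clinvar", "umd", "lovd", "rb1_db", "alsod", "brca_share", "locus_db"}
)


@dataclass(frozen=True)
class ClassifierConfig:
    specialty_sources: frozenset[str] = DEFAULT_SPECIALTY_SOURCES
    silver_sources: frozenset[str] = DEFAULT_SILVER_SOURCES
    min_stars: int = 2
    cterm_fraction_threshold: float = 0.90


@dataclass(frozen=True)
class MedalCall:
    """Classification outcome for one record."""

    record: VariantRecord
    bundle: EvidenceBundle
    germline_medal: Medal
    somatic_category: SomaticCategory
    reasons: tuple[str, ...]
    caution_cterm: bool
    pli_tier: PliTier
    retained_after_refinement: Optional[bool] = None

    # Convenience projections used by cohort summaries and reports.
    @property
    def key(self):
        return self.record.key

    @property
    def patient_id(self) -> str:
        return self.record.patient_id

    @property
    def gene_symbol(self) -> str:
        return self.bundle.gene.symbol

    @property
    def consequence(self):
        return self.bundle.consequence


def classify_germline(
    bundle: EvidenceBundle, config: ClassifierConfig = ClassifierConfig()
) -> tuple[Medal, tuple[str, ...]]:
    """Assign the germline medal for one evidence bundle.

    Returns (medal, ordered fired-rule labels).  Pure rule evaluation; no
    errors are raised.
    """
    cons = bundle.consequence
    truncating = cons.is_truncating
    pathogenic = [a for a in bundle.assertions if a.is_pathogenic]
    gene_disease = bundle.gene.lof_disease_mechanism or bundle.gene.is_tumor_suppressor

    starred = any(
        a.stars is not None and a.stars >= config.min_stars for a in pathogenic
    )
    specialty = any(a.source in config.specialty_sources for a in pathogenic)

    reasons: list[str] = []
    if (truncating or pathogenic) and gene_disease and (starred or specialty):
        if truncating:
            reasons.append(f"truncating:{cons.kind.value}")
        if pathogenic and not truncating:
            reasons.append("pathogenic_assertion")
        reasons.append("disease_gene")
        if starred:
            reasons.append("starred_assertion")
        if specialty:
            reasons.append("specialty_source")
        return Medal.GOLD, tuple(reasons)

    silver_shape = (
        cons.kind is Consequence.INFRAME_INDEL
        or (truncating and not bundle.gene.is_tumor_suppressor)
        or (cons.kind is Consequence.MISSENSE and bundle.insilico_tolerated is False)
    )
    any_source = any(a.source in config.silver_sources for a in bundle.assertions)
    if silver_shape and any_source:
        if cons.kind is Consequence.INFRAME_INDEL:
            reasons.append("inframe_indel")
        if truncating and not bundle.gene.is_tumor_suppressor:
            reasons.append("truncating_non_tsg")
        if cons.kind is Consequence.MISSENSE and bundle.insilico_tolerated is False:
            reasons.append("damaging_missense")
        reasons.append("database_match")
        return Medal.SILVER, tuple(reasons)

    if bundle.insilico_tolerated is True and not pathogenic:
        return Medal.BRONZE, ("insilico_tolerated",)

    return Medal.UNKNOWN, ()


def somatic_category(bundle: EvidenceBundle) -> SomaticCategory:
    """The somatic catalogue's category for the exact change; none if unmatched."""
    return bundle.somatic


def _round2_half_up(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def flag_cterm_caution(
    bundle: EvidenceBundle, config: ClassifierConfig = ClassifierConfig()
) -> bool:
    """C-terminal caution: truncation at >= 90% of the protein, or in the
    final coding exon.  The protein fraction is rounded half-up to two
    decimals before comparison, so a truncation at 89.95% of the protein
    counts as at the threshold.  Non-truncating consequences are never
    flagged."""
    cons = bundle.consequence
    if not cons.is_truncating:
        return False
    if cons.in_final_exon:
        return True
    frac = truncation_protein_fraction(cons, bundle.gene.protein_size)
    if frac is None:
        return False
    return _round2_half_up(frac) >= config.cterm_fraction_threshold


def pli_tier(pli: Optional[float]) -> PliTier:
    """gnomAD-style loss-of-function intolerance tier for a pLI value."""
    if pli is None:
        return PliTier.ABSENT
    if not (0.0 <= pli <= 1.0):
        raise ValueError(f"pLI must be in [0,1], got {pli}")
    if pli >= 0.9:
        return PliTier.HIGH
    if pli >= 0.5:
        return PliTier.INTERMEDIATE
    return PliTier.LOW


def classify_calls(
    annotated: Iterable[tuple[VariantRecord, EvidenceBundle]],
    config: ClassifierConfig = ClassifierConfig(),
) -> list[MedalCall]:
    """Classify annotated records and refine Silver calls in one pass."""
    calls = []
    for rec, bundle in annotated:
        medal, reasons = classify_germline(bundle, config)
        calls.append(
            MedalCall(
                record=rec,
                bundle=bundle,
                germline_medal=medal,
                somatic_category=somatic_category(bundle),
                reasons=reasons,
                caution_cterm=flag_cterm_caution(bundle, config),
                pli_tier=pli_tier(bundle.gene.pli),
            )
        )
    return refine_silver(calls)


def refine_silver(calls: Sequence[MedalCall]) -> list[MedalCall]:
    """Set ``retained_after_refinement`` on every call.

    Silver calls are retained only when the somatic catalogue categorises the
    same change Gold or Silver; Gold calls are always retained; for Bronze
    and Unknown the refinement does not apply (flag stays ``None``).
    """
    out = []
    for c in calls:
        if c.germline_medal is Medal.GOLD:
            retained = True
        elif c.germline_medal is Medal.SILVER:
            retained = c.somatic_category in (SomaticCategory.GOLD, SomaticCategory.SILVER)
        else:
            retained = None
        out.append(replace(c, retained_after_refinement=retained))
    return out
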