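"""Domain types and readers/writers for the variant-prioritization pipeline.

The pipeline consumes per-patient germline VCFs (GT + per-allele depths),
delimited evidence tables (pathogenicity assertions, somatic catalogue,
population frequencies, gene attributes), and produces a delimited medal
report.  Coordinates are 1-based and fully closed, matching VCF; the hg19
assembly is assumed throughout and no liftover is attempted.

The atom of the pipeline is :class:`VariantRecord`: one called variant in one
patient with its ref/alt read depths.  Chromosome X genotypes are treated as
diploid heterozygous (the cohort this pipeline was designed around is
all-female).
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pysam

logger = logging.getLogger("varmedal")

PathLike = Union[str, Path]

_ALLELE_RE = re.compile(r"^[ACGT]+$")


class ParseError(ValueError):
    """Malformed input file (names the file and, where known, the row)."""


class UndefinedValueError(ArithmeticError):
    """A ratio was requested on zero total depth."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class Genotype(str, Enum):
    HET = "het"
    HOM_ALT = "hom_alt"
    HOM_REF = "hom_ref"


class Consequence(str, Enum):
    """Variant consequence classes as carried by the input annotation.

    Consequences are consumed from an annotation column of the input (or the
    curated table); they are never recomputed from transcript models.
    """

    SPLICE = "splice"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    UTR5 = "utr5"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_REGION = "splice_region"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences treated as protein-truncating (splice included).
TRUNCATING = frozenset({Consequence.SPLICE, Consequence.FRAMESHIFT, Consequence.NONSENSE})


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a variant: chromosome, 1-based position, ref and alt allele."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for name, allele in (("ref", self.ref), ("alt", self.alt)):
            if not _ALLELE_RE.match(allele):
                raise ValueError(f"{name} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    @property
    def position(self) -> tuple[str, int]:
        """(chrom, pos) — the site, ignoring alleles."""
        return (self.chrom, self.pos)


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Numeric chromosomes first in numeric order, then X/Y/MT, then the rest."""
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (0, special[c], "")
    return (1, 0, c)


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one patient, with per-allele read support."""

    key: VariantKey
    patient_id: str
    ref_depth: Optional[int]
    alt_depth: Optional[int]
    genotype: Genotype
    caller_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for d in (self.ref_depth, self.alt_depth):
            if d is not None and d < 0:
                raise ValueError("read depths must be >= 0")

    @property
    def has_depths(self) -> bool:
        return self.ref_depth is not None and self.alt_depth is not None

    @property
    def total_depth(self) -> Optional[int]:
        if not self.has_depths:
            return None
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class ConsequenceClass:
    """A consequence with its protein-level change, as annotated upstream.

    ``aa_position`` is the residue index parsed from ``aa_change`` with a
    tolerant pattern (``S1848fs``, ``R175H``, ``Q678*``, ``E1892_E37`` splice
    codes); unparseable changes leave it absent.  ``in_final_exon`` marks a
    truncation annotated in the final coding exon (NMD-escape candidates).
    """

    kind: Consequence
    aa_change: Optional[str] = None
    aa_position: Optional[int] = None
    exon_code: Optional[str] = None
    in_final_exon: bool = False

    @property
    def is_truncating(self) -> bool:
        return self.kind in TRUNCATING


_AA_POS_RE = re.compile(r"^[A-Za-z*]?(\d+)")
_EXON_CODE_RE = re.compile(r"_((?:E|IVS)\d+)$")


def parse_aa_change(text: Optional[str]) -> tuple[Optional[int], Optional[str]]:
    """Parse a protein-change string into (residue index, exon code).

    Handles missense (``R175H``), frameshift (``S1848fs``), stop-gain
    (``Q678*``, with or without a space before ``*``), and splice residue+exon
    codes (``E1892_E37``).  Anything unparseable yields ``(None, None)``.
    """
    if text is None:
        return None, None
    t = text.replace(" ", "").strip()
    if not t:
        return None, None
    exon = None
    m = _EXON_CODE_RE.search(t)
    if m:
        exon = m.group(1)
    m = _AA_POS_RE.match(t)
    pos = int(m.group(1)) if m else None
    return pos, exon


@dataclass(frozen=True)
class GeneInfo:
    """Gene-level attributes used by the classifier and the pLI triage."""

    symbol: str
    in_panel: bool = False
    is_tumor_suppressor: bool = False
    lof_disease_mechanism: bool = False
    pli: Optional[float] = None
    protein_size: Optional[int] = None
    truncations_in_final_exon: bool = False

    def __post_init__(self) -> None:
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(f"pLI must be in [0,1], got {self.pli}")
        if self.protein_size is not None and self.protein_size < 1:
            raise ValueError("protein_size must be >= 1")


class AssertionClass(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    BENIGN = "benign"


#: Sources that carry a review-status star rating.
STAR_RATED_SOURCES = frozenset({"clinvar"})


@dataclass(frozen=True)
class PathogenicityAssertion:
    """One database assertion about a variant (e.g. a ClinVar record)."""

    key: VariantKey
    source: str
    classification: AssertionClass
    stars: Optional[int] = None

    def __post_init__(self) -> None:
        if self.stars is not None:
            if self.source not in STAR_RATED_SOURCES:
                raise ValueError(f"stars present for non-star-rated source {self.source!r}")
            if not (0 <= self.stars <= 4):
                raise ValueError(f"stars must be 0-4, got {self.stars}")

    @property
    def is_pathogenic(self) -> bool:
        return self.classification in (
            AssertionClass.PATHOGENIC,
            AssertionClass.LIKELY_PATHOGENIC,
        )


class SomaticCategory(str, Enum):
    GOLD = "gold"
    SILVER = "silver"
    NONE = "none"


@dataclass(frozen=True)
class SomaticMatch:
    key: VariantKey
    somatic_category: SomaticCategory = SomaticCategory.NONE


@dataclass(frozen=True)
class PopulationFrequency:
    key: VariantKey
    popmax_af: float = 0.0
    latino_af: Optional[float] = None

    def __post_init__(self) -> None:
        for af in (self.popmax_af, self.latino_af):
            if af is not None and not (0.0 <= af <= 1.0):
                raise ValueError(f"allele frequency must be in [0,1], got {af}")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and survival fields for one patient."""

    patient_id: str
    age_at_diagnosis: float
    family_history: bool
    subtype: str
    stage_advanced: bool
    bmi: float
    followup_months: float
    recurrence_event: bool
    death_event: bool

    def __post_init__(self) -> None:
        if self.age_at_diagnosis <= 0:
            raise ValueError("age_at_diagnosis must be > 0")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _genotype_for_alt(gt: Sequence[Optional[int]], alt_index: int) -> Genotype:
    called = [a for a in gt if a is not None]
    n_alt = sum(1 for a in called if a == alt_index)
    if called and n_alt == len(called):
        return Genotype.HOM_ALT
    if n_alt > 0:
        return Genotype.HET
    return Genotype.HOM_REF


def read_cohort_vcf(paths: Iterable[PathLike]) -> list[VariantRecord]:
    """Read per-patient VCFs into a flat list of :class:`VariantRecord`.

    Multi-allelic sites are split into one record per alternate allele with
    per-allele depths taken from AD (falling back to an RO/AO pair).  Records
    without usable depths are kept but flagged ``missing_depth`` and a warning
    is logged; downstream depth filters exclude them.
    """
    records: list[VariantRecord] = []
    for path in paths:
        path = str(path)
        try:
            vf = pysam.VariantFile(path)
        except (OSError, ValueError) as exc:
            raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc
        with vf:
            row = 0
            try:
                for rec in vf:
                    row += 1
                    records.extend(_records_from_site(rec, path))
            except (OSError, ValueError) as exc:
                raise ParseError(f"{path}: malformed VCF record after data line {row}: {exc}") from exc
    return records


def _records_from_site(rec: "pysam.VariantRecord", path: str) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    alts = rec.alts or ()
    flags = frozenset(f for f in rec.filter.keys() if f != "PASS")
    for sample_name, sample in rec.samples.items():
        gt = sample.get("GT") or ()
        ad = sample.get("AD")
        for i, alt in enumerate(alts, start=1):
            if alt is None or not _ALLELE_RE.match(alt):
                continue  # symbolic / spanning-deletion alleles are not variants here
            ref_depth = alt_depth = None
            sample_flags = flags
            if ad is not None and len(ad) > i and ad[0] is not None and ad[i] is not None:
                ref_depth, alt_depth = int(ad[0]), int(ad[i])
            else:
                ro, ao = sample.get("RO"), sample.get("AO")
                if ro is not None and ao is not None:
                    ao_i = ao[i - 1] if isinstance(ao, (tuple, list)) else ao
                    if ao_i is not None:
                        ref_depth, alt_depth = int(ro), int(ao_i)
            if ref_depth is None:
                sample_flags = flags | {"missing_depth"}
                logger.warning(
                    "%s: %s:%s %s>%s sample %s has no per-allele depths; "
                    "record excluded from depth-dependent filters",
                    path, rec.chrom, rec.pos, rec.ref, alt, sample_name,
                )
            out.append(
                VariantRecord(
                    key=VariantKey(chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt),
                    patient_id=sample_name,
                    ref_depth=ref_depth,
                    alt_depth=alt_depth,
                    genotype=_genotype_for_alt(gt, i),
                    caller_flags=sample_flags,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Curated-variant table (the bundled 50-row Gold table)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CuratedVariant:
    """One row of the curated Gold-variant table."""

    key: VariantKey
    patient_id: str
    ref_depth: int
    alt_depth: int
    gene: GeneInfo
    consequence: ConsequenceClass
    latino_af: Optional[float]
    reported_latin_america: Optional[bool]

    @property
    def gene_symbol(self) -> str:
        return self.gene.symbol

    @property
    def record(self) -> VariantRecord:
        """View of the row as a heterozygous VariantRecord (all rows are het)."""
        return VariantRecord(
            key=self.key,
            patient_id=self.patient_id,
            ref_depth=self.ref_depth,
            alt_depth=self.alt_depth,
            genotype=Genotype.HET,
        )


_CURATED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ref_depth", "alt_depth", "gene",
    "reported_la", "type", "aa_change", "patient", "pli", "af_lat", "prot_size",
]

_TYPE_MAP = {
    "splice": Consequence.SPLICE,
    "frameshift": Consequence.FRAMESHIFT,
    "nonsense": Consequence.NONSENSE,
    "missense": Consequence.MISSENSE,
    "utr_5": Consequence.UTR5,
    "utr5": Consequence.UTR5,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "splice_region": Consequence.SPLICE_REGION,
    "synonymous": Consequence.SYNONYMOUS,
}


def _parse_af(token: str) -> Optional[float]:
    """Parse an allele-frequency token; '-' means not observed (absent).

    Tokens for near-identical database variants keep only the numeric part
    (e.g. ``A:C 0`` -> 0.0); a trailing ``&`` marker is ignored.
    """
    t = token.strip().rstrip("&").strip()
    if t in ("", "-"):
        return None
    if ":" in t:
        t = t.split()[-1] if " " in t else t.rsplit(":", 1)[-1]
    return float(t)


def read_curated_table(path: PathLike) -> tuple[CuratedVariant, ...]:
    """Read a curated Gold-variant table (tab-separated, documented header)."""
    rows: list[CuratedVariant] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _CURATED_COLUMNS:
            raise ParseError(f"{path}: expected header {_CURATED_COLUMNS}, got {header}")
        for lineno, raw in enumerate(reader, start=2):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if len(raw) != len(_CURATED_COLUMNS):
                raise ParseError(
                    f"{path}: row {lineno} has {len(raw)} columns, expected {len(_CURATED_COLUMNS)}"
                )
            row = dict(zip(_CURATED_COLUMNS, (c.strip() for c in raw)))
            try:
                kind = _TYPE_MAP[row["type"].lower()]
                aa_pos, exon = parse_aa_change(row["aa_change"] or None)
                pli = float(row["pli"]) if row["pli"] not in ("", "-") else None
                gene = GeneInfo(
                    symbol=row["gene"],
                    in_panel=True,
                    pli=pli,
                    protein_size=int(row["prot_size"]),
                )
                # blank LA column = previously reported in Latin-American cohorts
                la = row["reported_la"]
                rows.append(
                    CuratedVariant(
                        key=VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"]),
                        patient_id=row["patient"],
                        ref_depth=int(row["ref_depth"]),
                        alt_depth=int(row["alt_depth"]),
                        gene=gene,
                        consequence=ConsequenceClass(
                            kind=kind,
                            aa_change=row["aa_change"] or None,
                            aa_position=aa_pos,
                            exon_code=exon,
                        ),
                        latino_af=_parse_af(row["af_lat"]),
                        reported_latin_america=la.lower() != "no",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: row {lineno}: {exc}") from exc
    return tuple(rows)


def apply_gene_attributes(
    rows: Sequence[CuratedVariant], attributes: dict[str, GeneInfo]
) -> tuple[CuratedVariant, ...]:
    """Merge gene-attribute flags (TSG / LoF-mechanism / final-exon) onto rows."""
    out = []
    for r in rows:
        attr = attributes.get(r.gene.symbol)
        if attr is None:
            out.append(r)
            continue
        gene = replace(
            r.gene,
            is_tumor_suppressor=attr.is_tumor_suppressor,
            lof_disease_mechanism=attr.lof_disease_mechanism,
            truncations_in_final_exon=attr.truncations_in_final_exon,
        )
        cons = r.consequence
        if attr.truncations_in_final_exon and cons.is_truncating:
            cons = replace(cons, in_final_exon=True)
        out.append(replace(r, gene=gene, consequence=cons))
    return tuple(out)


def read_gene_attributes(path: PathLike) -> dict[str, GeneInfo]:
    """Read a gene-attribute table: symbol, TSG, LoF-mechanism, pLI, size, final-exon."""
    attrs: dict[str, GeneInfo] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            pli = row.get("pli", "").strip()
            size = row.get("protein_size", "").strip()
            attrs[row["symbol"]] = GeneInfo(
                symbol=row["symbol"],
                in_panel=True,
                is_tumor_suppressor=row["is_tumor_suppressor"].strip() == "1",
                lof_disease_mechanism=row["lof_disease_mechanism"].strip() == "1",
                pli=float(pli) if pli not in ("", "-") else None,
                protein_size=int(size) if size not in ("", "-") else None,
                truncations_in_final_exon=row.get("truncations_in_final_exon", "0").strip() == "1",
            )
    return attrs


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "chrom", "pos", "ref", "alt", "patient", "gene", "consequence",
    "germline_medal", "somatic_category", "retained", "caution_cterm",
    "pli_tier", "reasons",
]


@dataclass(frozen=True)
class ReportRow:
    chrom: str
    pos: int
    ref: str
    alt: str
    patient: str
    gene: str
    consequence: str
    germline_medal: str
    somatic_category: str
    retained: str
    caution_cterm: bool
    pli_tier: str
    reasons: tuple[str, ...]


def report_rows(calls: Iterable) -> list[ReportRow]:
    """Project medal calls onto sorted, deterministic report rows."""
    rows = [
        ReportRow(
            chrom=c.record.key.chrom,
            pos=c.record.key.pos,
            ref=c.record.key.ref,
            alt=c.record.key.alt,
            patient=c.record.patient_id,
            gene=c.bundle.gene.symbol,
            consequence=c.bundle.consequence.kind.value,
            germline_medal=c.germline_medal.value,
            somatic_category=c.somatic_category.value,
            retained="" if c.retained_after_refinement is None else str(c.retained_after_refinement).lower(),
            caution_cterm=c.caution_cterm,
            pli_tier=c.pli_tier.value,
            reasons=tuple(c.reasons),
        )
        for c in calls
    ]
    rows.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.patient, r.ref, r.alt))
    return rows


def write_report(calls: Iterable, path: PathLike) -> None:
    """Write classified calls as a sorted TSV; byte-identical across runs."""
    rows = report_rows(calls)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(REPORT_COLUMNS)
        for r in rows:
            w.writerow([
                r.chrom, r.pos, r.ref, r.alt, r.patient, r.gene, r.consequence,
                r.germline_medal, r.somatic_category, r.retained,
                str(r.caution_cterm).lower(), r.pli_tier, ";".join(r.reasons),
            ])


def read_report(path: PathLike) -> list[ReportRow]:
    """Read back a report written by :func:`write_report`."""
    rows: list[ReportRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                ReportRow(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    patient=row["patient"],
                    gene=row["gene"],
                    consequence=row["consequence"],
                    germline_medal=row["germline_medal"],
                    somatic_category=row["somatic_category"],
                    retained=row["retained"],
                    caution_cterm=row["caution_cterm"] == "true",
                    pli_tier=row["pli_tier"],
                    reasons=tuple(s for s in row["reasons"].split(";") if s),
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Patient covariate table
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = [
    "patient_id", "age_at_diagnosis", "family_history", "subtype",
    "stage_advanced", "bmi", "followup_months", "recurrence_event", "death_event",
]


def write_patient_table(patients: Iterable[PatientRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PATIENT_COLUMNS)
        for p in sorted(patients, key=lambda p: p.patient_id):
            w.writerow([
                p.patient_id, f"{p.age_at_diagnosis:.2f}", int(p.family_history),
                p.subtype, int(p.stage_advanced), f"{p.bmi:.2f}",
                f"{p.followup_months:.2f}", int(p.recurrence_event), int(p.death_event),
            ])


def read_patient_table(path: PathLike) -> list[PatientRecord]:
    patients: list[PatientRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    age_at_diagnosis=float(row["age_at_diagnosis"]),
                    family_history=row["family_history"] == "1",
                    subtype=row["subtype"],
                    stage_advanced=row["stage_advanced"] == "1",
                    bmi=float(row["bmi"]),
                    followup_months=float(row["followup_months"]),
                    recurrence_event=row["recurrence_event"] == "1",
                    death_event=row["death_event"] == "1",
                )
            )
    return patients
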