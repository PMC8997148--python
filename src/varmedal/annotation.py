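"""Join variants to evidence: panel, consequences, assertions, somatic
catalogue, population frequencies, gene attributes; protein-coordinate
features.

The gene panel is the union of two or more configured gene lists (the study
design unions an internal cancer-predisposition set with the Cancer Gene
Census; 712 + 723 symbols with 573 shared gives the 862-gene panel).  Records
in genes outside the panel are dropped.  Evidence absent from the tables is
represented explicitly (empty assertion list, somatic ``none``, popmax 0)
rather than by missing fields, so the classifier is a pure function of the
bundle.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .model_io import (
    AssertionClass,
    Consequence,
    ConsequenceClass,
    GeneInfo,
    ParseError,
    PathLike,
    PathogenicityAssertion,
    PopulationFrequency,
    SomaticCategory,
    VariantKey,
    VariantRecord,
    parse_aa_change,
    read_gene_attributes,
)

logger = logging.getLogger("varmedal")

__all__ = [
    "GenePanel",
    "EvidenceBundle",
    "EvidenceTables",
    "build_panel",
    "read_gene_list",
    "annotate",
    "truncation_protein_fraction",
    "read_evidence_dir",
]


@dataclass(frozen=True)
class GenePanel:
    """A named set of gene symbols (case-normalized to upper case)."""

    name: str
    symbols: frozenset[str]

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


def build_panel(lists: Sequence[Iterable[str]], name: str = "panel") -> GenePanel:
    """Union two or more gene lists into one panel."""
    symbols: set[str] = set()
    for lst in lists:
        symbols.update(s.strip().upper() for s in lst if s.strip())
    if not symbols:
        raise ValueError("panel union is empty")
    return GenePanel(name=name, symbols=frozenset(symbols))


def read_gene_list(path: PathLike) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out


@dataclass(frozen=True)
class EvidenceBundle:
    """All evidence joined onto one (variant, gene) pair."""

    key: VariantKey
    consequence: ConsequenceClass
    gene: GeneInfo
    assertions: tuple[PathogenicityAssertion, ...] = ()
    somatic: SomaticCategory = SomaticCategory.NONE
    popfreq: PopulationFrequency = None  # type: ignore[assignment]
    insilico_tolerated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.popfreq is None:
            object.__setattr__(self, "popfreq", PopulationFrequency(key=self.key))


@dataclass
class EvidenceTables:
    """In-memory evidence, keyed by variant or gene symbol."""

    gene_by_key: dict[VariantKey, str] = field(default_factory=dict)
    consequence_by_key: dict[VariantKey, ConsequenceClass] = field(default_factory=dict)
    gene_info: dict[str, GeneInfo] = field(default_factory=dict)
    assertions: dict[VariantKey, tuple[PathogenicityAssertion, ...]] = field(default_factory=dict)
    somatic: dict[VariantKey, SomaticCategory] = field(default_factory=dict)
    popfreq: dict[VariantKey, PopulationFrequency] = field(default_factory=dict)
    tolerated: dict[VariantKey, bool] = field(default_factory=dict)


def annotate(
    records: Iterable[VariantRecord],
    panel: GenePanel,
    tables: EvidenceTables,
) -> list[tuple[VariantRecord, EvidenceBundle]]:
    """Join each record to its evidence bundle; drop off-panel records.

    Records with no gene assignment are logged and dropped.  Absent evidence
    becomes explicit defaults: no assertions, somatic ``none``, popmax 0,
    in-silico prediction unknown.
    """
    out: list[tuple[VariantRecord, EvidenceBundle]] = []
    for rec in records:
        symbol = tables.gene_by_key.get(rec.key)
        if symbol is None:
            logger.warning("no gene assignment for %s; dropped", rec.key)
            continue
        if symbol not in panel:
            continue
        gene = tables.gene_info.get(symbol, GeneInfo(symbol=symbol))
        gene = GeneInfo(
            symbol=gene.symbol,
            in_panel=True,
            is_tumor_suppressor=gene.is_tumor_suppressor,
            lof_disease_mechanism=gene.lof_disease_mechanism,
            pli=gene.pli,
            protein_size=gene.protein_size,
            truncations_in_final_exon=gene.truncations_in_final_exon,
        )
        consequence = tables.consequence_by_key.get(rec.key, ConsequenceClass(kind=Consequence.OTHER))
        if gene.truncations_in_final_exon and consequence.is_truncating and not consequence.in_final_exon:
            consequence = ConsequenceClass(
                kind=consequence.kind,
                aa_change=consequence.aa_change,
                aa_position=consequence.aa_position,
                exon_code=consequence.exon_code,
                in_final_exon=True,
            )
        bundle = EvidenceBundle(
            key=rec.key,
            consequence=consequence,
            gene=gene,
            assertions=tables.assertions.get(rec.key, ()),
            somatic=tables.somatic.get(rec.key, SomaticCategory.NONE),
            popfreq=tables.popfreq.get(rec.key, PopulationFrequency(key=rec.key)),
            insilico_tolerated=tables.tolerated.get(rec.key),
        )
        out.append((rec, bundle))
    return out


def truncation_protein_fraction(
    consequence: ConsequenceClass, protein_size: Optional[int]
) -> Optional[float]:
    """Fraction of the protein N-terminal of a truncation: aa_position / size.

    Defined only for truncating consequences with a parseable residue index
    and a known protein length; in (0, 1], equal to 1.0 when the truncation
    falls on the final residue.  Anything else yields ``None``.
    """
    if not consequence.is_truncating:
        return None
    if consequence.aa_position is None or protein_size is None or protein_size < 1:
        return None
    if consequence.aa_position > protein_size:
        return None
    return consequence.aa_position / protein_size


# ---------------------------------------------------------------------------
# Evidence-directory reading (TSVs keyed by chrom/pos/ref/alt)
# ---------------------------------------------------------------------------


def _key_from_row(row: Mapping[str, str]) -> VariantKey:
    return VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])


def read_evidence_dir(path: PathLike) -> EvidenceTables:
    """Load an evidence directory written by the simulator (or hand-built).

    Expected files: ``variants.tsv`` (gene/consequence/tolerated per variant),
    ``assertions.tsv``, ``somatic.tsv``, ``popfreq.tsv``, ``gene_info.tsv``.
    Missing optional files leave the corresponding table empty.
    """
    path = Path(path)
    tables = EvidenceTables()

    variants = path / "variants.tsv"
    if variants.exists():
        with open(variants, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = _key_from_row(row)
                tables.gene_by_key[key] = row["gene"].upper()
                aa = row.get("aa_change", "").strip() or None
                aa_pos, exon = parse_aa_change(aa)
                tables.consequence_by_key[key] = ConsequenceClass(
                    kind=Consequence(row["consequence"]),
                    aa_change=aa,
                    aa_position=aa_pos,
                    exon_code=exon,
                    in_final_exon=row.get("in_final_exon", "0").strip() == "1",
                )
                tol = row.get("tolerated", "").strip()
                if tol in ("0", "1"):
                    tables.tolerated[key] = tol == "1"

    gene_info = path / "gene_info.tsv"
    if gene_info.exists():
        tables.gene_info = {
            sym.upper(): info for sym, info in read_gene_attributes(gene_info).items()
        }

    assertions = path / "assertions.tsv"
    if assertions.exists():
        with open(assertions, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = _key_from_row(row)
                stars = row.get("stars", "").strip()
                a = PathogenicityAssertion(
                    key=key,
                    source=row["source"],
                    classification=AssertionClass(row["classification"]),
                    stars=int(stars) if stars != "" else None,
                )
                tables.assertions[key] = tables.assertions.get(key, ()) + (a,)

    somatic = path / "somatic.tsv"
    if somatic.exists():
        with open(somatic, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                tables.somatic[_key_from_row(row)] = SomaticCategory(row["somatic_category"])

    popfreq = path / "popfreq.tsv"
    if popfreq.exists():
        with open(popfreq, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                key = _key_from_row(row)
                lat = row.get("latino_af", "").strip()
                tables.popfreq[key] = PopulationFrequency(
                    key=key,
                    popmax_af=float(row["popmax_af"]),
                    latino_af=float(lat) if lat not in ("", "-") else None,
                )
    return tables
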