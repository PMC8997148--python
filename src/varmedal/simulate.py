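"""Synthetic cohorts with the statistical structure the pipeline assumes.

The study's raw data are not deposited, so everything the pipeline consumes
can be generated here: per-patient VCFs, evidence tables, gene panels,
clinical covariates, survival times, and per-variant truth labels.  The
generator plants, against a background of a ~115-patient cohort:

* **Gold-like** variants — rare (popmax < 0.01) truncations in
  disease-associated tumor-suppressor panel genes with 2-star pathogenic
  ClinVar-type assertions; most carriers get one, ~28% get two.
* **Silver-like** variants — in-frame indels in non-tumor-suppressor panel
  genes with a single locus-database assertion; a configurable fraction also
  match the somatic catalogue (and hence survive Silver refinement).
* **Bronze-like** variants — missense changes predicted tolerated.
* **Artifact positions** — recurrent positions with several carriers, two or
  more distinct alternate alleles, and a systematic alternate-read deficit.
* **Common positions** — one variant carried by every patient.
* Low-quality and off-panel background records exercising the filter funnel.

Read depths follow a negative-binomial-shaped integer model (mean 40,
matching the magnitude of real exome depth pairs); heterozygous alternate
fractions are symmetric around 0.5.  Planted true variants are drawn so they
pass the read-support filters.  Carrier status shifts covariates by the
configured odds multipliers and scales the event hazard, so association and
survival analyses can be validated by parameter recovery.  All randomness
flows from a single seeded generator; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import csv

import numpy as np
import pysam

from .annotation import EvidenceTables, GenePanel, build_panel
from .model_io import (
    AssertionClass,
    Consequence,
    ConsequenceClass,
    CuratedVariant,
    GeneInfo,
    Genotype,
    PathLike,
    PathogenicityAssertion,
    PatientRecord,
    PopulationFrequency,
    SomaticCategory,
    VariantKey,
    VariantRecord,
    apply_gene_attributes,
    chrom_sort_key,
    parse_aa_change,
    read_curated_table,
    read_gene_attributes,
    write_patient_table,
)

__all__ = [
    "SimConfig",
    "TruthLabels",
    "SimulatedCohort",
    "simulate_patients",
    "simulate_cohort",
    "write_cohort",
    "gold_table_fixture",
    "gene_attributes_fixture",
]

_SUBTYPES = ("LuminalB_Her2neg", "TripleNegative", "LuminalB_Her2pos", "Her2_nonluminal", "LuminalA")
_SUBTYPE_P = (0.28, 0.28, 0.13, 0.07, 0.24)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    n_patients: int = 115
    panel_list_sizes: tuple[int, int] = (712, 723)
    panel_overlap: int = 573  # union = 712 + 723 - 573 = 862 genes
    n_gold_like: int = 49
    n_silver_like: int = 106
    n_bronze_like: int = 60
    n_artifact_positions: int = 2
    n_common_positions: int = 1
    n_lowqual: int = 40
    n_offpanel: int = 30
    frac_carriers_two: float = 0.28
    frac_silver_somatic: float = 0.5
    artifact_carriers: int = 6
    artifact_n_alts: int = 3
    depth_mean: float = 40.0
    depth_dispersion: float = 8.0
    het_vaf_concentration: float = 40.0
    carrier_effect: dict = field(
        default_factory=lambda: {"family_history": 3.21, "age_lt30": 3.74, "bmi_per_unit": 1.19}
    )
    survival_hazard_ratio: float = 2.5
    baseline_hazard_per_month: float = 0.0019
    carrier_prevalence: float = 0.34
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_patients, self.n_gold_like, self.n_silver_like, self.n_bronze_like,
            self.n_artifact_positions, self.n_common_positions, self.n_lowqual, self.n_offpanel,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        panel_size = sum(self.panel_list_sizes) - self.panel_overlap
        n_planted_genes = self.n_gold_like + self.n_silver_like + self.n_bronze_like + \
            self.n_artifact_positions + self.n_common_positions + self.n_lowqual
        if n_planted_genes > panel_size:
            raise ValueError(
                f"infeasible config: {n_planted_genes} planted panel variants exceed "
                f"the {panel_size} panel genes"
            )


@dataclass(frozen=True)
class TruthLabels:
    """Intended class per planted variant; carrier status per patient."""

    variant_class: dict[VariantKey, str]
    patient_carrier: dict[str, bool]

    @property
    def gold_keys(self) -> set[VariantKey]:
        return {k for k, v in self.variant_class.items() if v == "gold"}


@dataclass
class SimulatedCohort:
    config: SimConfig
    patient_ids: tuple[str, ...]
    records: list[VariantRecord]
    tables: EvidenceTables
    panel_lists: tuple[list[str], list[str]]
    panel: GenePanel
    patients: list[PatientRecord]
    truth: TruthLabels


# ---------------------------------------------------------------------------
# Covariates and survival
# ---------------------------------------------------------------------------


def _binary_given_carrier(rng, carrier: np.ndarray, p0: float, odds_ratio: float) -> np.ndarray:
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    p = np.where(carrier, p1, p0)
    return rng.random(carrier.size) < p


def simulate_patients(
    config: SimConfig,
    carrier: Optional[np.ndarray] = None,
    rng: Optional[np.random.Generator] = None,
    patient_ids: Optional[tuple[str, ...]] = None,
) -> tuple[list[PatientRecord], dict[str, bool]]:
    """Draw covariates and survival for a cohort, conditional on carrier status.

    If ``carrier`` is omitted, carrier flags are Bernoulli at the configured
    prevalence.  Binary covariates are drawn so the carrier/non-carrier odds
    ratio equals the configured multiplier; BMI is shifted in carriers by
    sd^2 * ln(OR per unit), the normal-covariate equivalent.  Event times are
    exponential with the carrier hazard scaled by the hazard ratio; censoring
    is uniform over a 48–73 month follow-up window.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_patients
    if patient_ids is None:
        patient_ids = tuple(f"P{i:04d}" for i in range(1, n + 1))
    if carrier is None:
        carrier = rng.random(n) < config.carrier_prevalence
    carrier = np.asarray(carrier, dtype=bool)

    eff = config.carrier_effect
    fh = _binary_given_carrier(rng, carrier, 0.25, eff.get("family_history", 1.0))
    lt30 = _binary_given_carrier(rng, carrier, 0.15, eff.get("age_lt30", 1.0))
    age = np.where(lt30, rng.uniform(24.0, 29.9, n), rng.uniform(30.0, 40.0, n))
    stage = rng.random(n) < 0.60
    subtype = rng.choice(_SUBTYPES, size=n, p=_SUBTYPE_P)
    bmi_sd = 4.0
    bmi_shift = bmi_sd**2 * math.log(eff.get("bmi_per_unit", 1.0))
    bmi = rng.normal(26.5, bmi_sd, n) + np.where(carrier, bmi_shift, 0.0)
    bmi = np.clip(bmi, 15.0, 55.0)

    rate = config.baseline_hazard_per_month * np.where(carrier, config.survival_hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(48.0, 73.0, n)
    observed = event_time <= censor_time
    followup = np.minimum(event_time, censor_time)
    death = observed & (rng.random(n) < 0.5)

    patients = [
        PatientRecord(
            patient_id=pid,
            age_at_diagnosis=float(age[i]),
            family_history=bool(fh[i]),
            subtype=str(subtype[i]),
            stage_advanced=bool(stage[i]),
            bmi=float(bmi[i]),
            followup_months=float(followup[i]),
            recurrence_event=bool(observed[i]),
            death_event=bool(death[i]),
        )
        for i, pid in enumerate(patient_ids)
    ]
    return patients, {pid: bool(carrier[i]) for i, pid in enumerate(patient_ids)}


# ---------------------------------------------------------------------------
# Variant planting
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


def _site(gene_index: int, offset: int = 0) -> tuple[str, int, str, str]:
    chrom = str((gene_index % 22) + 1)
    pos = 1_000_000 + gene_index * 10_000 + offset
    ref = _BASES[gene_index % 4]
    alt = _BASES[(gene_index + 1 + offset) % 4]
    if alt == ref:
        alt = _BASES[(gene_index + 2 + offset) % 4]
    return chrom, pos, ref, alt


def _draw_het_depths(rng: np.random.Generator, config: SimConfig) -> tuple[int, int]:
    """Depths for a planted true heterozygote; guaranteed to pass all read filters."""
    k = config.depth_dispersion
    p = k / (k + config.depth_mean)
    a = config.het_vaf_concentration / 2.0
    for _ in range(1000):
        total = int(rng.negative_binomial(k, p))
        if total < 21:
            continue
        frac = rng.beta(a, a)
        alt = int(rng.binomial(total, frac))
        ref = total - alt
        v = alt / total
        if alt >= 10 and ref >= 1 and 0.25 <= v <= 0.75:
            return ref, alt
    raise RuntimeError("could not draw passing depths; depth model misconfigured")


def _gene_info(symbol: str, rng: np.random.Generator, tsg: bool) -> GeneInfo:
    return GeneInfo(
        symbol=symbol,
        in_panel=True,
        is_tumor_suppressor=tsg,
        lof_disease_mechanism=True,
        pli=float(np.round(rng.uniform(0.0, 1.0), 2)),
        protein_size=int(rng.integers(300, 3000)),
    )


def simulate_cohort(config: SimConfig = SimConfig()) -> SimulatedCohort:
    """Generate a full cohort: records, evidence, panels, covariates, truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patient_ids = tuple(f"P{i:04d}" for i in range(1, n + 1))

    size_a, size_b = config.panel_list_sizes
    union_size = size_a + size_b - config.panel_overlap
    all_panel = [f"GENE{i:04d}" for i in range(1, union_size + 1)]
    list_a = all_panel[:size_a]
    list_b = all_panel[size_a - config.panel_overlap:]
    panel = build_panel([list_a, list_b], name="synthetic-union")

    tables = EvidenceTables()
    records: list[VariantRecord] = []
    variant_class: dict[VariantKey, str] = {}
    gene_cursor = 0

    def next_gene(tsg: bool) -> GeneInfo:
        nonlocal gene_cursor
        gene_cursor += 1
        info = _gene_info(all_panel[gene_cursor - 1], rng, tsg)
        tables.gene_info[info.symbol] = info
        return info

    def add_het_record(key: VariantKey, pid: str) -> None:
        ref_d, alt_d = _draw_het_depths(rng, config)
        records.append(
            VariantRecord(key=key, patient_id=pid, ref_depth=ref_d, alt_depth=alt_d,
                          genotype=Genotype.HET)
        )

    # --- Gold-like: truncations in TSG/LoF genes with 2-star assertions ---
    truncating_kinds = (Consequence.SPLICE, Consequence.FRAMESHIFT, Consequence.NONSENSE)
    n_two = int(round(config.n_gold_like * config.frac_carriers_two / (1 + config.frac_carriers_two)))
    n_single = config.n_gold_like - 2 * n_two
    if n_single < 0:
        raise ValueError("frac_carriers_two too high for n_gold_like")
    n_carriers = n_single + n_two
    if n_carriers > n:
        raise ValueError("infeasible config: more Gold carriers than patients")
    carrier_ids = list(rng.choice(n, size=n_carriers, replace=False))
    gold_patient_seq = [patient_ids[i] for i in carrier_ids]
    gold_patient_seq += [patient_ids[i] for i in carrier_ids[:n_two]]

    for v, pid in enumerate(gold_patient_seq):
        gene = next_gene(tsg=True)
        kind = truncating_kinds[v % 3]
        chrom, pos, ref, alt = _site(gene_cursor)
        key = VariantKey(chrom, pos, ref, alt)
        aa_pos = int(rng.uniform(0.30, 0.70) * gene.protein_size)
        aa_pos = max(aa_pos, 1)
        suffix = {"splice": f"_E{int(rng.integers(2, 30))}", "frameshift": "fs", "nonsense": "*"}[kind.value]
        tables.gene_by_key[key] = gene.symbol
        tables.consequence_by_key[key] = ConsequenceClass(
            kind=kind, aa_change=f"S{aa_pos}{suffix}", aa_position=aa_pos,
        )
        tables.assertions[key] = (
            PathogenicityAssertion(key=key, source="clinvar",
                                   classification=AssertionClass.PATHOGENIC, stars=2),
        )
        tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=1e-4, latino_af=1e-4)
        variant_class[key] = "gold"
        add_het_record(key, pid)

    # --- Silver-like: in-frame indels in non-TSG genes, single-source match ---
    for v in range(config.n_silver_like):
        gene = next_gene(tsg=False)
        chrom, pos, ref, alt = _site(gene_cursor)
        key = VariantKey(chrom, pos, ref, alt)
        aa_pos = int(rng.uniform(0.2, 0.8) * gene.protein_size) or 1
        tables.gene_by_key[key] = gene.symbol
        tables.consequence_by_key[key] = ConsequenceClass(
            kind=Consequence.INFRAME_INDEL, aa_change=f"K{aa_pos}del", aa_position=aa_pos,
        )
        tables.assertions[key] = (
            PathogenicityAssertion(key=key, source="lovd", classification=AssertionClass.VUS),
        )
        if rng.random() < config.frac_silver_somatic:
            tables.somatic[key] = SomaticCategory.GOLD if rng.random() < 0.5 else SomaticCategory.SILVER
        tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=1e-4)
        variant_class[key] = "silver"
        add_het_record(key, patient_ids[int(rng.integers(0, n))])

    # --- Bronze-like: tolerated missense, no assertions ---
    for v in range(config.n_bronze_like):
        gene = next_gene(tsg=False)
        chrom, pos, ref, alt = _site(gene_cursor)
        key = VariantKey(chrom, pos, ref, alt)
        tables.gene_by_key[key] = gene.symbol
        tables.consequence_by_key[key] = ConsequenceClass(kind=Consequence.MISSENSE, aa_change="R100H",
                                                          aa_position=100)
        tables.tolerated[key] = True
        tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=5e-4)
        variant_class[key] = "bronze"
        add_het_record(key, patient_ids[int(rng.integers(0, n))])

    # --- Artifact positions: varied alt alleles, systematic alt-read deficit ---
    for v in range(config.n_artifact_positions):
        gene = next_gene(tsg=True)
        chrom, pos, ref, _ = _site(gene_cursor)
        alts = [b for b in _BASES if b != ref][: config.artifact_n_alts]
        carriers = rng.choice(n, size=config.artifact_carriers, replace=False)
        for j, pi in enumerate(carriers):
            alt = alts[j % len(alts)]
            key = VariantKey(chrom, pos, ref, alt)
            if key not in tables.gene_by_key:
                tables.gene_by_key[key] = gene.symbol
                tables.consequence_by_key[key] = ConsequenceClass(
                    kind=Consequence.FRAMESHIFT, aa_change="S200fs", aa_position=200
                )
                tables.assertions[key] = (
                    PathogenicityAssertion(key=key, source="clinvar",
                                           classification=AssertionClass.PATHOGENIC, stars=2),
                )
                tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=0.0)
                variant_class[key] = "artifact"
            # alt deficit: alt reads strictly below ref, still past the filters
            # (alt >= ref/3 keeps VAF >= 0.25 so only curation removes these)
            ref_d = int(rng.integers(28, 36))
            alt_d = int(rng.integers(max(11, ref_d // 3 + 1), int(ref_d * 0.8) + 1))
            records.append(
                VariantRecord(key=key, patient_id=patient_ids[pi], ref_depth=ref_d,
                              alt_depth=alt_d, genotype=Genotype.HET)
            )

    # --- Common positions: carried by every patient ---
    for v in range(config.n_common_positions):
        gene = next_gene(tsg=True)
        chrom, pos, ref, alt = _site(gene_cursor)
        key = VariantKey(chrom, pos, ref, alt)
        tables.gene_by_key[key] = gene.symbol
        tables.consequence_by_key[key] = ConsequenceClass(kind=Consequence.FRAMESHIFT,
                                                          aa_change="A300fs", aa_position=300)
        tables.assertions[key] = (
            PathogenicityAssertion(key=key, source="clinvar",
                                   classification=AssertionClass.PATHOGENIC, stars=2),
        )
        tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=0.0)
        variant_class[key] = "common"
        for pid in patient_ids:
            add_het_record(key, pid)

    # --- Low-quality background: removed by the caller filters ---
    for v in range(config.n_lowqual):
        gene = next_gene(tsg=True)
        chrom, pos, ref, alt = _site(gene_cursor)
        key = VariantKey(chrom, pos, ref, alt)
        tables.gene_by_key[key] = gene.symbol
        tables.consequence_by_key[key] = ConsequenceClass(kind=Consequence.NONSENSE,
                                                          aa_change="Q50*", aa_position=50)
        mode = v % 3
        if mode == 0:  # shallow site
            ref_d, alt_d = int(rng.integers(2, 5)), int(rng.integers(1, 4))
        elif mode == 1:  # extreme allele balance
            ref_d, alt_d = int(rng.integers(60, 90)), int(rng.integers(1, 5))
        else:  # too common in the population
            ref_d, alt_d = _draw_het_depths(rng, config)
            tables.popfreq[key] = PopulationFrequency(key=key, popmax_af=0.05)
        variant_class[key] = "lowqual"
        records.append(
            VariantRecord(key=key, patient_id=patient_ids[int(rng.integers(0, n))],
                          ref_depth=ref_d, alt_depth=alt_d, genotype=Genotype.HET)
        )

    # --- Off-panel background: dropped at panel restriction ---
    for v in range(config.n_offpanel):
        symbol = f"OFFG{v:04d}"
        tables.gene_info[symbol] = GeneInfo(symbol=symbol, in_panel=False)
        chrom = str((v % 22) + 1)
        pos = 900_000 + v * 97
        ref = _BASES[v % 4]
        alt = _BASES[(v + 2) % 4]
        key = VariantKey(chrom, pos, ref, alt)
        tables.gene_by_key[key] = symbol
        tables.consequence_by_key[key] = ConsequenceClass(kind=Consequence.MISSENSE)
        variant_class[key] = "offpanel"
        ref_d, alt_d = _draw_het_depths(rng, config)
        records.append(
            VariantRecord(key=key, patient_id=patient_ids[int(rng.integers(0, n))],
                          ref_depth=ref_d, alt_depth=alt_d, genotype=Genotype.HET)
        )

    carrier_flags = np.array([pid in set(gold_patient_seq) for pid in patient_ids])
    patients, carrier_map = simulate_patients(config, carrier=carrier_flags, rng=rng,
                                              patient_ids=patient_ids)

    records.sort(key=lambda r: (chrom_sort_key(r.key.chrom), r.key.pos, r.key.alt, r.patient_id))
    return SimulatedCohort(
        config=config,
        patient_ids=patient_ids,
        records=records,
        tables=tables,
        panel_lists=(list_a, list_b),
        panel=panel,
        patients=patients,
        truth=TruthLabels(variant_class=variant_class, patient_carrier=carrier_map),
    )


# ---------------------------------------------------------------------------
# On-disk layout: vcf/, evidence/, covariates.tsv, truth/
# ---------------------------------------------------------------------------


def _write_vcf(path: Path, patient_id: str, records: list[VariantRecord]) -> None:
    header = pysam.VariantHeader()
    for c in [str(i) for i in range(1, 23)] + ["X", "Y"]:
        header.add_line(f"##contig=<ID={c},length=250000000>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_sample(patient_id)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for rec in sorted(records, key=lambda r: (chrom_sort_key(r.key.chrom), r.key.pos, r.key.alt)):
            site = vf.new_record(
                contig=rec.key.chrom,
                start=rec.key.pos - 1,
                stop=rec.key.pos - 1 + len(rec.key.ref),
                alleles=(rec.key.ref, rec.key.alt),
            )
            gt = {"het": (0, 1), "hom_alt": (1, 1), "hom_ref": (0, 0)}[rec.genotype.value]
            site.samples[patient_id]["GT"] = gt
            if rec.has_depths:
                site.samples[patient_id]["AD"] = (rec.ref_depth, rec.alt_depth)
            vf.write(site)


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def write_cohort(cohort: SimulatedCohort, out_dir: PathLike) -> Path:
    """Write a simulated cohort as a directory tree of plain-text files.

    Layout: ``vcf/<patient>.vcf``, ``evidence/*.tsv``, ``panel_a.txt``,
    ``panel_b.txt``, ``covariates.tsv``, ``truth/*.tsv``.  Deterministic:
    the same cohort object always produces identical bytes.
    """
    out = Path(out_dir)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    (out / "evidence").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    by_patient: dict[str, list[VariantRecord]] = {pid: [] for pid in cohort.patient_ids}
    for rec in cohort.records:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    for pid, recs in by_patient.items():
        _write_vcf(out / "vcf" / f"{pid}.vcf", pid, recs)

    t = cohort.tables
    keys = sorted(t.gene_by_key, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.alt))
    _write_tsv(
        out / "evidence" / "variants.tsv",
        ["chrom", "pos", "ref", "alt", "gene", "consequence", "aa_change", "in_final_exon", "tolerated"],
        [
            [
                k.chrom, k.pos, k.ref, k.alt, t.gene_by_key[k],
                t.consequence_by_key[k].kind.value,
                t.consequence_by_key[k].aa_change or "",
                int(t.consequence_by_key[k].in_final_exon),
                "" if k not in t.tolerated else int(t.tolerated[k]),
            ]
            for k in keys
        ],
    )
    _write_tsv(
        out / "evidence" / "gene_info.tsv",
        ["symbol", "is_tumor_suppressor", "lof_disease_mechanism", "pli", "protein_size",
         "truncations_in_final_exon"],
        [
            [
                g.symbol, int(g.is_tumor_suppressor), int(g.lof_disease_mechanism),
                "-" if g.pli is None else g.pli,
                "-" if g.protein_size is None else g.protein_size,
                int(g.truncations_in_final_exon),
            ]
            for g in sorted(t.gene_info.values(), key=lambda g: g.symbol)
        ],
    )
    _write_tsv(
        out / "evidence" / "assertions.tsv",
        ["chrom", "pos", "ref", "alt", "source", "classification", "stars"],
        [
            [k.chrom, k.pos, k.ref, k.alt, a.source, a.classification.value,
             "" if a.stars is None else a.stars]
            for k in sorted(t.assertions, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.alt))
            for a in t.assertions[k]
        ],
    )
    _write_tsv(
        out / "evidence" / "somatic.tsv",
        ["chrom", "pos", "ref", "alt", "somatic_category"],
        [
            [k.chrom, k.pos, k.ref, k.alt, t.somatic[k].value]
            for k in sorted(t.somatic, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.alt))
        ],
    )
    _write_tsv(
        out / "evidence" / "popfreq.tsv",
        ["chrom", "pos", "ref", "alt", "popmax_af", "latino_af"],
        [
            [k.chrom, k.pos, k.ref, k.alt, repr(t.popfreq[k].popmax_af),
             "" if t.popfreq[k].latino_af is None else repr(t.popfreq[k].latino_af)]
            for k in sorted(t.popfreq, key=lambda k: (chrom_sort_key(k.chrom), k.pos, k.alt))
        ],
    )
    for name, genes in zip(("panel_a.txt", "panel_b.txt"), cohort.panel_lists):
        (out / name).write_text("\n".join(genes) + "\n")
    write_patient_table(cohort.patients, out / "covariates.tsv")
    _write_tsv(
        out / "truth" / "variants.tsv",
        ["chrom", "pos", "ref", "alt", "class"],
        [
            [k.chrom, k.pos, k.ref, k.alt, v]
            for k, v in sorted(cohort.truth.variant_class.items(),
                               key=lambda kv: (chrom_sort_key(kv[0].chrom), kv[0].pos, kv[0].alt))
        ],
    )
    _write_tsv(
        out / "truth" / "carriers.tsv",
        ["patient_id", "carrier"],
        [[pid, int(c)] for pid, c in sorted(cohort.truth.patient_carrier.items())],
    )
    return out


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return resources.files("varmedal.data").joinpath(name)


def gene_attributes_fixture() -> dict[str, GeneInfo]:
    """Gene attributes (TSG / LoF-mechanism / final-exon flags) for the genes
    in the bundled curated table."""
    with resources.as_file(_data_path("gene_attributes.tsv")) as p:
        return read_gene_attributes(p)


def gold_table_fixture() -> tuple[CuratedVariant, ...]:
    """The bundled 50-row curated Gold-variant table, with gene attributes
    merged on.  Returned as an immutable tuple of frozen rows."""
    with resources.as_file(_data_path("gold_variants_table.tsv")) as p:
        rows = read_curated_table(p)
    return apply_gene_attributes(rows, gene_attributes_fixture())
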