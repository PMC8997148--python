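"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import textwrap

import pytest

from varmedal import (
    AssertionClass,
    Consequence,
    ConsequenceClass,
    EvidenceBundle,
    GeneInfo,
    Genotype,
    PathogenicityAssertion,
    PopulationFrequency,
    SomaticCategory,
    VariantKey,
    VariantRecord,
    gold_table_fixture,
)

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=11,length=135006516>
    ##contig=<ID=13,length=115169878>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
    """)


def write_vcf(path, body: str, sample: str = "H4") -> str:
    path.write_text(VCF_HEADER.format(sample=sample) + body)
    return str(path)


def make_key(chrom="1", pos=1000, ref="A", alt="T") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)


def make_record(
    chrom="1", pos=1000, ref="A", alt="T", patient="P1",
    ref_depth=30, alt_depth=25, genotype=Genotype.HET,
) -> VariantRecord:
    return VariantRecord(
        key=VariantKey(chrom, pos, ref, alt),
        patient_id=patient,
        ref_depth=ref_depth,
        alt_depth=alt_depth,
        genotype=genotype,
    )


def make_bundle(
    kind=Consequence.FRAMESHIFT,
    aa_position=500,
    protein_size=1000,
    tsg=True,
    lof=True,
    pli=None,
    assertions=(),
    somatic=SomaticCategory.NONE,
    tolerated=None,
    in_final_exon=False,
    key=None,
) -> EvidenceBundle:
    key = key or make_key()
    return EvidenceBundle(
        key=key,
        consequence=ConsequenceClass(kind=kind, aa_position=aa_position, in_final_exon=in_final_exon),
        gene=GeneInfo(
            symbol="GENE1", in_panel=True, is_tumor_suppressor=tsg,
            lof_disease_mechanism=lof, pli=pli, protein_size=protein_size,
        ),
        assertions=tuple(assertions),
        somatic=somatic,
        popfreq=PopulationFrequency(key=key),
        insilico_tolerated=tolerated,
    )


def pathogenic(key=None, source="clinvar", stars=2) -> PathogenicityAssertion:
    return PathogenicityAssertion(
        key=key or make_key(), source=source,
        classification=AssertionClass.PATHOGENIC,
        stars=stars if source == "clinvar" else None,
    )


def vus(key=None, source="lovd") -> PathogenicityAssertion:
    return PathogenicityAssertion(
        key=key or make_key(), source=source, classification=AssertionClass.VUS
    )


@pytest.fixture(scope="session")
def gold_table():
    return gold_table_fixture()


@pytest.fixture(scope="session")
def gold_table_by_gene(gold_table):
    by_gene: dict[str, list] = {}
    for row in gold_table:
        by_gene.setdefault(row.gene_symbol, []).append(row)
    return by_gene
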