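import numpy as np
import pytest

from mutpanel.maf_io import (
    Cohort,
    MutationRecord,
    VariantClassification,
    VariantType,
)


def snv(sample, gene, chrom, start, ref, alt,
        cls=VariantClassification.MISSENSE, protein=None):
    return MutationRecord(
        sample_id=sample, gene_symbol=gene, chromosome=chrom,
        start=start, end=start, ref_allele=ref, alt_allele=alt,
        variant_type=VariantType.SNV, variant_classification=cls,
        protein_change=protein,
    )


@pytest.fixture
def f1_cohort():
    """Four-patient worked example: two KRAS alt alleles collapse into one
    locus; KRAS and TP53 tie at prevalence 0.5, BRAF sits at 0.25."""
    records = [
        snv("P1", "KRAS", "12", 25398285, "G", "A", protein="p.G12D"),
        snv("P1", "TP53", "17", 7578406, "C", "T"),
        snv("P2", "KRAS", "12", 25398285, "G", "T", protein="p.G12V"),
        snv("P3", "TP53", "17", 7578406, "C", "T"),
        snv("P4", "BRAF", "7", 140453136, "A", "T"),
    ]
    return Cohort(records=records, samples=frozenset({"P1", "P2", "P3", "P4"}),
                  name="F1")


@pytest.fixture
def q_cohort():
    """Two-patient validation cohort sharing only the KRAS locus with F1."""
    records = [
        snv("Q1", "KRAS", "12", 25398285, "G", "A"),
        snv("Q2", "EGFR", "7", 55259515, "T", "G"),
    ]
    return Cohort(records=records, samples=frozenset({"Q1", "Q2"}), name="Q")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
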