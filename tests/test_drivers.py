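"""Driver-gene matrix, coverage, waterfall, associations, protein tallies."""

import math

import numpy as np
import pytest

from helpers_oracles import fisher_two_sided
from mutpanel.drivers import (
    AlterationClass,
    DEFAULT_ONCOGENES,
    DEFAULT_SUPPRESSORS,
    Direction,
    build_alteration_matrix,
    gene_set_coverage,
    load_gene_lists,
    pairwise_association,
    parse_protein_position,
    protein_position_tally,
    sort_waterfall,
)
from mutpanel.maf_io import Cohort, VariantClassification
from mutpanel.simulate import SyntheticSpec, generate_cohort

from conftest import snv


def test_default_gene_lists_shape():
    assert len(DEFAULT_ONCOGENES) == 14
    assert len(DEFAULT_SUPPRESSORS) == 9
    assert {"KRAS", "EGFR", "DDR2", "BRAF", "MET", "PIK3CA"} <= set(DEFAULT_ONCOGENES)
    assert {"TP53", "CDKN2A"} <= set(DEFAULT_SUPPRESSORS)


def test_load_gene_lists_yaml(tmp_path):
    p = tmp_path / "genes.yaml"
    p.write_text("oncogenes: [KRAS, EGFR]\nsuppressors: [TP53]\n")
    onc, sup = load_gene_lists(p)
    assert onc == ["KRAS", "EGFR"] and sup == ["TP53"]


def test_empty_cohort_matrix_all_zero():
    cohort = Cohort(records=[], samples=frozenset({"P1", "P2"}))
    m = build_alteration_matrix(cohort, genes=["KRAS", "TP53"])
    assert m.cells == {}
    assert m.burden == {"P1": 0, "P2": 0}


def test_mutation_and_cna_combine_in_one_cell_burden_counts_genes():
    cohort = Cohort(
        records=[snv("P1", "KRAS", "12", 25398285, "G", "A")],
        samples=frozenset({"P1"}),
    )
    m = build_alteration_matrix(
        cohort, cna={("P1", "KRAS"): 2}, genes=["KRAS", "TP53"]
    )
    assert m.cells[("P1", "KRAS")] == {AlterationClass.MISSENSE, AlterationClass.AMP}
    assert m.burden["P1"] == 1  # one altered gene, not two classes


def test_classification_to_alteration_mapping():
    records = [
        snv("P1", "TP53", "17", 100, "C", "T", cls=VariantClassification.NONSENSE),
        snv("P2", "TP53", "17", 101, "C", "T", cls=VariantClassification.SPLICE),
        snv("P3", "TP53", "17", 102, "C", "T", cls=VariantClassification.SILENT),
        snv("P4", "TP53", "17", 103, "C", "T", cls=VariantClassification.OTHER),
    ]
    m = build_alteration_matrix(
        Cohort(records=records, samples=frozenset({"P1", "P2", "P3", "P4"})),
        genes=["TP53"],
    )
    assert m.cells[("P1", "TP53")] == {AlterationClass.TRUNCATING}
    assert m.cells[("P2", "TP53")] == {AlterationClass.TRUNCATING}
    assert ("P3", "TP53") not in m.cells  # silent never an alteration
    assert ("P4", "TP53") not in m.cells


def test_shallow_cna_excluded_by_default():
    cohort = Cohort(records=[], samples=frozenset({"P1"}))
    cna = {("P1", "EGFR"): 1, ("P1", "TP53"): -1}
    m = build_alteration_matrix(cohort, cna=cna, genes=["EGFR", "TP53"])
    assert m.cells == {}
    m2 = build_alteration_matrix(
        cohort, cna=cna, genes=["EGFR", "TP53"], include_shallow_cna=True
    )
    assert m2.cells[("P1", "EGFR")] == {AlterationClass.AMP}
    assert m2.cells[("P1", "TP53")] == {AlterationClass.DEEP_DEL}


@pytest.fixture
def four_patient_matrix():
    # P1 altered in 2 genes, P2 in 2, P3 in 1, P4 in 0
    records = [
        snv("P1", "KRAS", "12", 1, "G", "A"),
        snv("P1", "TP53", "17", 2, "C", "T", cls=VariantClassification.NONSENSE),
        snv("P2", "KRAS", "12", 1, "G", "T"),
        snv("P2", "EGFR", "7", 3, "T", "G"),
        snv("P3", "TP53", "17", 2, "C", "T"),
    ]
    cohort = Cohort(records=records,
                    samples=frozenset({"P1", "P2", "P3", "P4"}))
    return build_alteration_matrix(cohort, genes=["KRAS", "TP53", "EGFR"])


def test_gene_set_coverage_hand_counts(four_patient_matrix):
    m = four_patient_matrix
    assert gene_set_coverage(m, ["KRAS", "TP53", "EGFR"], min_genes=1) == 0.75
    assert gene_set_coverage(m, ["KRAS", "TP53", "EGFR"], min_genes=2) == 0.5
    assert gene_set_coverage(m, ["EGFR"], min_genes=1) == 0.25


def test_coverage_min1_equals_nonzero_burden_fraction(four_patient_matrix):
    m = four_patient_matrix
    frac = sum(1 for b in m.burden.values() if b > 0) / len(m.patients)
    assert gene_set_coverage(m, m.genes, min_genes=1) == frac


def test_waterfall_descending_burden_ties_lexicographic(four_patient_matrix):
    assert sort_waterfall(four_patient_matrix) == ["P1", "P2", "P3", "P4"]


def test_waterfall_all_equal_is_lexicographic():
    cohort = Cohort(records=[], samples=frozenset({"B", "A", "C"}))
    m = build_alteration_matrix(cohort, genes=["KRAS"])
    assert sort_waterfall(m) == ["A", "B", "C"]


def test_waterfall_random_matrix_nonincreasing(rng):
    spec = SyntheticSpec(
        n_patients=80, passenger_locus_count=0, passenger_burden_mean=0.0,
        exclusivity_pairs=[("GA", "GB", 0.4, 0.3, 1.0), ("GC", "GD", 0.2, 0.5, 1.0)],
        seed=9,
    )
    cohort, _ = generate_cohort(spec)
    m = build_alteration_matrix(cohort, genes=["GA", "GB", "GC", "GD"])
    order = sort_waterfall(m)
    burdens = [m.burden[p] for p in order]
    assert sorted(order) == sorted(m.patients)
    assert all(a >= b for a, b in zip(burdens, burdens[1:]))


def _matrix_from_sets(n, set_a, set_b):
    records = []
    for p in set_a:
        records.append(snv(f"P{p}", "GA", "1", 10, "G", "A"))
    for p in set_b:
        records.append(snv(f"P{p}", "GB", "2", 20, "C", "T"))
    cohort = Cohort(records=records,
                    samples=frozenset(f"P{i}" for i in range(n)))
    return build_alteration_matrix(cohort, genes=["GA", "GB"])


def test_fisher_p_and_or_against_enumeration_oracle():
    # (both=3, a=1, b=1, neither=3), n=8
    m = _matrix_from_sets(8, {0, 1, 2, 3}, {0, 1, 2, 4})
    (assoc,) = pairwise_association(m)
    assert (assoc.both, assoc.a_only, assoc.b_only, assoc.neither) == (3, 1, 1, 3)
    assert assoc.p_value == pytest.approx(fisher_two_sided(3, 1, 1, 3), abs=1e-12)
    assert assoc.log_odds_ratio == pytest.approx(math.log(9.0))


def test_fisher_oracle_agreement_on_small_tables():
    m_tables = [
        (a, b, c, d)
        for a in range(6) for b in range(6) for c in range(6) for d in range(6)
        if 0 < a + b < a + b + c + d and 0 < a + c < a + b + c + d
    ]
    for a, b, c, d in m_tables[::7]:  # systematic subsample for speed
        n = a + b + c + d
        set_a = set(range(a + b))
        set_b = set(range(a)) | set(range(a + b, a + b + c))
        m = _matrix_from_sets(n, set_a, set_b)
        (assoc,) = pairwise_association(m)
        assert assoc.p_value == pytest.approx(
            fisher_two_sided(a, b, c, d), abs=1e-9
        ), (a, b, c, d)


def test_degenerate_gene_flagged():
    m = _matrix_from_sets(6, set(), {0, 1})
    (assoc,) = pairwise_association(m)
    assert assoc.degenerate and assoc.p_value == 1.0
    assert assoc.direction is Direction.NONE


def test_perfect_cooccurrence_detected():
    m = _matrix_from_sets(30, set(range(8)), set(range(8)))
    (assoc,) = pairwise_association(m)
    assert assoc.log_odds_ratio > 0
    assert assoc.direction is Direction.CO_OCCURRENCE


def test_bh_qvalues_monotone_and_dominate_p(rng):
    spec = SyntheticSpec(
        n_patients=120, passenger_locus_count=0, passenger_burden_mean=0.0,
        exclusivity_pairs=[
            ("G1", "G2", 0.3, 0.3, 0.2), ("G3", "G4", 0.3, 0.3, 1.0),
            ("G5", "G6", 0.25, 0.25, 4.0),
        ],
        seed=13,
    )
    cohort, _ = generate_cohort(spec)
    m = build_alteration_matrix(cohort, genes=[f"G{i}" for i in range(1, 7)])
    assocs = pairwise_association(m)
    assert all(a.q_value >= a.p_value - 1e-15 for a in assocs)
    by_p = sorted(assocs, key=lambda a: a.p_value)
    qs = [a.q_value for a in by_p]
    assert all(q1 <= q2 + 1e-15 for q1, q2 in zip(qs, qs[1:]))


def test_planted_exclusivity_recovered():
    hits = 0
    for seed in range(20):
        spec = SyntheticSpec(
            n_patients=500, passenger_locus_count=0, passenger_burden_mean=0.0,
            exclusivity_pairs=[("GA", "GB", 0.3, 0.3, 0.1)], seed=seed,
        )
        cohort, _ = generate_cohort(spec)
        m = build_alteration_matrix(cohort, genes=["GA", "GB"])
        (assoc,) = pairwise_association(m, alpha=0.05)
        if assoc.direction is Direction.MUTUAL_EXCLUSIVITY:
            hits += 1
    assert hits >= 19


# --- protein-position tallies -------------------------------------------------

@pytest.mark.parametrize(
    "change,pos",
    [
        ("p.G12D", 12), ("p.E746_A750del", 746), ("p.Q61*", 61),
        ("p.F507fs", 507), ("p.X125_splice", 125), ("p.T790M", 790),
        (None, None), ("", None), ("oddball", None),
    ],
)
def test_parse_protein_position(change, pos):
    assert parse_protein_position(change) == pos


def test_tally_hand_counts():
    records = [
        snv("P1", "KRAS", "12", 1, "G", "A", protein="p.G12D"),
        snv("P2", "KRAS", "12", 1, "G", "T", protein="p.G12V"),
        snv("P3", "KRAS", "12", 2, "G", "T", protein="p.G13C"),
    ]
    cohort = Cohort(records=records, samples=frozenset({"P1", "P2", "P3"}))
    tally = protein_position_tally(cohort, "KRAS")
    t = tally.counts.set_index("position")
    assert t.loc[12, "MISSENSE"] == 2 and t.loc[13, "MISSENSE"] == 1
    assert tally.unmapped == 0
    pos, count, frac = tally.top_position()
    assert (pos, count) == (12, 2) and frac == pytest.approx(2 / 3)


def test_tally_unparseable_goes_to_unmapped_not_dropped():
    records = [
        snv("P1", "EGFR", "7", 1, "T", "G", protein=None),
        snv("P2", "EGFR", "7", 2, "T", "G", protein="?"),
    ]
    cohort = Cohort(records=records, samples=frozenset({"P1", "P2"}))
    tally = protein_position_tally(cohort, "EGFR")
    assert tally.unmapped == 2
    assert tally.counts.empty
    assert tally.top_position() is None


def test_tally_absent_gene_empty():
    cohort = Cohort(records=[], samples=frozenset({"P1"}))
    tally = protein_position_tally(cohort, "NOPE")
    assert tally.counts.empty and tally.unmapped == 0


def test_tally_classes_by_classification():
    records = [
        snv("P1", "TP53", "17", 1, "C", "T", protein="p.R175H"),
        snv("P2", "TP53", "17", 2, "C", "T",
            cls=VariantClassification.NONSENSE, protein="p.R196*"),
    ]
    cohort = Cohort(records=records, samples=frozenset({"P1", "P2"}))
    t = protein_position_tally(cohort, "TP53").counts.set_index("position")
    assert t.loc[175, "MISSENSE"] == 1
    assert t.loc[196, "TRUNCATING"] == 1
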