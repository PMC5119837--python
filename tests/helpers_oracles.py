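"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the Fisher oracle is an
exact integer enumeration over all 2x2 tables with fixed margins, and the
coverage oracle is a nested per-patient scan over raw records.
"""

from __future__ import annotations

from math import comb

from mutpanel.maf_io import Cohort, VariantClassification


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing the (exact, integer) probabilities of every table at
    most as probable as the observed one."""
    n = a + b + c + d
    row = a + b
    col = a + c
    lo = max(0, row + col - n)
    hi = min(row, col)
    denom = comb(n, col)
    nums = {x: comb(row, x) * comb(n - row, col - x) for x in range(lo, hi + 1)}
    obs = nums[a]
    return sum(v for v in nums.values() if v <= obs) / denom


def brute_force_depths(
    panel_keys: set, cohort: Cohort, include_silent: bool = False
) -> dict[str, int]:
    """Per-patient count of distinct panel loci hit, by nested scan."""
    depths = {}
    for s in cohort.samples:
        hit = set()
        for r in cohort.records:
            if r.sample_id != s:
                continue
            if not include_silent and (
                r.variant_classification is VariantClassification.SILENT
            ):
                continue
            key = (r.gene_symbol, r.chromosome, r.start)
            if key in panel_keys:
                hit.add(key)
        depths[s] = len(hit)
    return depths


def brute_force_coverage(
    panel_keys: set, cohort: Cohort, depths: list[int], include_silent: bool = False
) -> dict[int, float]:
    d_map = brute_force_depths(panel_keys, cohort, include_silent)
    n = len(d_map)
    return {d: sum(1 for v in d_map.values() if v >= d) / n for d in depths}


def distinct_patient_locus_pairs(cohort: Cohort, include_silent: bool = False) -> int:
    """Number of distinct (patient, gene, start) triples among eligible records."""
    triples = set()
    for r in cohort.records:
        if not include_silent and (
            r.variant_classification is VariantClassification.SILENT
        ):
            continue
        triples.add((r.sample_id, r.gene_symbol, r.chromosome, r.start))
    return len(triples)
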