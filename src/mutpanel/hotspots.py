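"""Collapse mutation records into recurrently mutated loci and rank them.

A *locus* is keyed by (gene symbol, chromosome, genomic start); distinct alt
alleles and variant types at the same start collapse into one locus, matching
the annotation scheme ``gene_start`` (KRAS_25398285 aggregates all G12
substitutions).  A locus's *prevalence* is the fraction of cohort patients
carrying at least one eligible mutation there — each patient counts once per
locus no matter how many rows they contribute.  Ranking is by descending
prevalence with a deterministic lexicographic tie-break.

Silent (synonymous) mutations are excluded by default: panel design targets
the non-synonymous classes.  ``include_silent=True`` re-includes them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .maf_io import Cohort, MutationRecord, VariantClassification, VariantType

__all__ = ["Locus", "eligible_records", "aggregate_loci", "rank_loci", "loci_table", "write_loci_tsv"]


@dataclass(frozen=True)
class Locus:
    """A collapsed recurrently mutated genomic position.

    ``substitution_counts`` tallies "ref>alt" classes over the SNV records
    only; indel records contribute to ``variant_type_counts`` but not to the
    substitution spectrum.
    """

    gene_symbol: str
    chromosome: str
    start: int
    patient_set: frozenset[str]
    prevalence: float
    n_records: int
    variant_type_counts: tuple[tuple[VariantType, int], ...]
    substitution_counts: tuple[tuple[str, int], ...]
    ref_allele: Optional[str] = None  # set only in strict (allele-keyed) mode
    alt_allele: Optional[str] = None

    @property
    def key(self) -> tuple:
        if self.ref_allele is not None:
            return (self.gene_symbol, self.chromosome, self.start,
                    self.ref_allele, self.alt_allele)
        return (self.gene_symbol, self.chromosome, self.start)

    @property
    def label(self) -> str:
        base = f"{self.gene_symbol}_{self.start}"
        if self.ref_allele is not None:
            return f"{base}_{self.ref_allele}>{self.alt_allele}"
        return base

    @property
    def n_patients(self) -> int:
        return len(self.patient_set)

    def type_counts(self) -> dict[VariantType, int]:
        return dict(self.variant_type_counts)

    def subst_counts(self) -> dict[str, int]:
        return dict(self.substitution_counts)


def eligible_records(
    cohort: Cohort, include_silent: bool = False
) -> list[MutationRecord]:
    """Records that enter hotspot statistics (silent excluded by default)."""
    if include_silent:
        return list(cohort.records)
    return [
        r
        for r in cohort.records
        if r.variant_classification is not VariantClassification.SILENT
    ]


def aggregate_loci(
    cohort: Cohort,
    include_silent: bool = False,
    strict: bool = False,
) -> list[Locus]:
    """One :class:`Locus` per distinct (gene, chromosome, start).

    ``strict=True`` additionally keys on (ref, alt) so that each specific
    substitution is its own locus.  Prevalence denominators come from the
    cohort's sample universe, so mutation-free patients dilute every locus.
    """
    if cohort.n_samples == 0:
        raise ValueError("cohort has an empty sample universe")
    groups: dict[tuple, list[MutationRecord]] = defaultdict(list)
    for r in eligible_records(cohort, include_silent):
        if strict:
            key = (r.gene_symbol, r.chromosome, r.start, r.ref_allele, r.alt_allele)
        else:
            key = (r.gene_symbol, r.chromosome, r.start)
        groups[key].append(r)

    n = cohort.n_samples
    loci: list[Locus] = []
    for key, recs in groups.items():
        patients = frozenset(r.sample_id for r in recs)
        tcounts: dict[VariantType, int] = defaultdict(int)
        scounts: dict[str, int] = defaultdict(int)
        for r in recs:
            tcounts[r.variant_type] += 1
            if r.variant_type is VariantType.SNV:
                scounts[f"{r.ref_allele}>{r.alt_allele}"] += 1
        loci.append(
            Locus(
                gene_symbol=key[0],
                chromosome=key[1],
                start=key[2],
                patient_set=patients,
                prevalence=len(patients) / n,
                n_records=len(recs),
                variant_type_counts=tuple(sorted(tcounts.items(), key=lambda kv: kv[0].value)),
                substitution_counts=tuple(sorted(scounts.items())),
                ref_allele=key[3] if strict else None,
                alt_allele=key[4] if strict else None,
            )
        )
    return loci


def rank_loci(loci: Iterable[Locus]) -> list[Locus]:
    """Descending prevalence; ties broken by (gene, chromosome, start) ascending.

    The ordering is total and deterministic, hence invariant to input order.
    """
    return sorted(
        loci,
        key=lambda l: (-l.prevalence, l.gene_symbol, l.chromosome, l.start),
    )


def loci_table(loci: Iterable[Locus]) -> pd.DataFrame:
    rows = []
    for rank, l in enumerate(loci, start=1):
        tc = l.type_counts()
        rows.append(
            {
                "rank": rank,
                "label": l.label,
                "gene": l.gene_symbol,
                "chrom": l.chromosome,
                "start": l.start,
                "n_patients": l.n_patients,
                "prevalence": l.prevalence,
                "n_records": l.n_records,
                "n_snv": tc.get(VariantType.SNV, 0),
                "n_ins": tc.get(VariantType.INS, 0),
                "n_del": tc.get(VariantType.DEL, 0),
                "n_other": tc.get(VariantType.OTHER, 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "label", "gene", "chrom", "start", "n_patients",
            "prevalence", "n_records", "n_snv", "n_ins", "n_del", "n_other",
        ],
    )


def write_loci_tsv(loci: Iterable[Locus], path: str | Path) -> None:
    loci_table(loci).to_csv(path, sep="\t", index=False)
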