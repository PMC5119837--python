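"""Apply a discovery-cohort panel to an independent validation cohort.

Loci are matched exactly on (gene symbol, chromosome, start); the gene symbol
is kept in the key to disambiguate positions across annotation versions
(``match_on_position=True`` drops it).  No coordinate tolerance is applied,
so both cohorts must share a genome build — a heuristic warning fires when
more than 90% of panel loci are absent from the validation cohort, the
signature of a build mismatch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .hotspots import aggregate_loci
from .maf_io import Cohort
from .panels import CoverageProfile, Panel, coverage_profile

logger = logging.getLogger("mutpanel")

__all__ = ["CrossCohortReport", "apply_panel", "prevalence_comparison"]


@dataclass
class CrossCohortReport:
    """Coverage and per-locus prevalences of a panel in a validation cohort."""

    panel: Panel
    validation_cohort: str
    coverage_at: dict[int, float]
    profile: CoverageProfile
    per_locus: pd.DataFrame  # label, gene, chrom, start, prevalence_discovery, prevalence_validation
    absent_loci: list[str]


def _validation_prevalences(
    panel: Panel, validation: Cohort, include_silent: bool, match_on_position: bool
) -> list[float]:
    val_loci = aggregate_loci(validation, include_silent=include_silent)
    if match_on_position:
        by_key = {}
        for l in val_loci:
            key = (l.chromosome, l.start)
            # merge patient sets if two symbols share a position
            prev = by_key.get(key, frozenset())
            by_key[key] = prev | l.patient_set
        return [
            len(by_key.get((l.chromosome, l.start), ())) / validation.n_samples
            for l in panel.loci
        ]
    by_key = {(l.gene_symbol, l.chromosome, l.start): l for l in val_loci}
    return [
        by_key[(l.gene_symbol, l.chromosome, l.start)].prevalence
        if (l.gene_symbol, l.chromosome, l.start) in by_key
        else 0.0
        for l in panel.loci
    ]


def apply_panel(
    panel: Panel,
    validation: Cohort,
    depths: Sequence[int] = (1, 2, 5, 10),
    include_silent: bool = False,
    match_on_position: bool = False,
) -> CrossCohortReport:
    """Coverage of a panel in an independent cohort, plus per-locus prevalences.

    Applying a panel to its own discovery cohort reproduces the self-coverage
    numbers of :func:`mutpanel.panels.coverage_profile` exactly.
    """
    profile = coverage_profile(
        panel, validation, depths=depths, include_silent=include_silent
    )
    prev_val = _validation_prevalences(
        panel, validation, include_silent, match_on_position
    )
    per_locus = pd.DataFrame(
        {
            "label": [l.label for l in panel.loci],
            "gene": [l.gene_symbol for l in panel.loci],
            "chrom": [l.chromosome for l in panel.loci],
            "start": [l.start for l in panel.loci],
            "prevalence_discovery": [l.prevalence for l in panel.loci],
            "prevalence_validation": prev_val,
        }
    )
    absent = [l.label for l, p in zip(panel.loci, prev_val) if p == 0.0]
    if panel.k > 0 and len(absent) / panel.k > 0.9:
        logger.warning(
            "%.0f%% of panel loci absent from cohort %r: possible genome-build "
            "mismatch between discovery and validation data",
            100 * len(absent) / panel.k, validation.name,
        )
    return CrossCohortReport(
        panel=panel,
        validation_cohort=validation.name,
        coverage_at=profile.coverage_at,
        profile=profile,
        per_locus=per_locus,
        absent_loci=absent,
    )


def prevalence_comparison(
    panel_top_n: Panel,
    cohort_a: Cohort,
    cohort_b: Cohort,
    include_silent: bool = False,
) -> pd.DataFrame:
    """Side-by-side prevalences of the top-n loci in two cohorts.

    ``prevalence_a`` is recomputed from ``cohort_a`` (not taken from the
    panel) so the comparison is symmetric; loci never mutated in ``cohort_b``
    are flagged ``absent_in_b``.
    """
    prev_a = _validation_prevalences(panel_top_n, cohort_a, include_silent, False)
    prev_b = _validation_prevalences(panel_top_n, cohort_b, include_silent, False)
    df = pd.DataFrame(
        {
            "label": [l.label for l in panel_top_n.loci],
            "gene": [l.gene_symbol for l in panel_top_n.loci],
            "chrom": [l.chromosome for l in panel_top_n.loci],
            "start": [l.start for l in panel_top_n.loci],
            "prevalence_a": prev_a,
            "prevalence_b": prev_b,
        }
    )
    df["absent_in_b"] = df["prevalence_b"] == 0.0
    return df
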