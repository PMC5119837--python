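"""Top-k hotspot panels and their coverage / depth / composition statistics.

A *panel* is the first k loci of a prevalence ranking.  For a patient, the
*depth* is the number of distinct panel loci at which they carry at least one
eligible mutation (a locus-targeted assay detects a hotspot once, however
many alt alleles sit there; ``count_records=True`` switches to raw row
counting).  *Coverage at depth d* is the fraction of the sample universe with
depth >= d, computed over ALL samples including mutation-free ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hotspots import Locus, eligible_records
from .maf_io import Cohort, VariantType

logger = logging.getLogger("mutpanel")

__all__ = [
    "Panel",
    "CoverageProfile",
    "PanelComposition",
    "build_panel",
    "coverage_profile",
    "coverage_curve",
    "panel_composition",
    "depth_summary",
    "write_panel_tsv",
    "SUBSTITUTION_CLASSES",
    "COLLAPSED_CLASSES",
]

# 12 ordered base-substitution classes, and the 6 pyrimidine-reference
# classes used when complementary strands are collapsed.
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
COLLAPSED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def collapse_substitution(cls: str) -> str:
    """Fold a substitution onto the pyrimidine reference strand (G>T -> C>A)."""
    ref, alt = cls.split(">")
    if ref in ("C", "T"):
        return cls
    return f"{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"


@dataclass(frozen=True)
class Panel:
    """An ordered fixed-size list of hotspot loci."""

    loci: tuple[Locus, ...]
    source_cohort: str = "cohort"

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def keys(self) -> tuple[tuple, ...]:
        return tuple(l.key for l in self.loci)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l.label for l in self.loci)


@dataclass
class CoverageProfile:
    """Per-patient panel depths and coverage at a set of depth thresholds."""

    depth_by_patient: dict[str, int]
    coverage_at: dict[int, float]
    mean_depth: float
    median_depth: float
    sd_depth: float


@dataclass
class PanelComposition:
    """Variant-type mix of panel loci and the SNV substitution spectrum."""

    type_fractions: dict[str, float]
    substitution_fractions: dict[str, float]


def build_panel(ranked: Sequence[Locus], k: int, source_cohort: str = "cohort") -> Panel:
    """First k loci of a ranking, order preserved."""
    if k < 1:
        raise ValueError(f"panel size must be >= 1, got {k}")
    if k > len(ranked):
        raise ValueError(
            f"requested panel size {k} exceeds the {len(ranked)} available loci"
        )
    return Panel(loci=tuple(ranked[:k]), source_cohort=source_cohort)


def _patient_depths(
    panel_keys: frozenset, cohort: Cohort, include_silent: bool, count_records: bool
) -> dict[str, int]:
    depths = {s: 0 for s in cohort.samples}
    if count_records:
        for r in eligible_records(cohort, include_silent):
            if (r.gene_symbol, r.chromosome, r.start) in panel_keys:
                depths[r.sample_id] += 1
    else:
        hit: dict[str, set] = {}
        for r in eligible_records(cohort, include_silent):
            key = (r.gene_symbol, r.chromosome, r.start)
            if key in panel_keys:
                hit.setdefault(r.sample_id, set()).add(key)
        for s, keys in hit.items():
            depths[s] = len(keys)
    return depths


def coverage_profile(
    panel: Panel,
    cohort: Cohort,
    depths: Sequence[int] = (1, 2, 5, 10),
    include_silent: bool = False,
    count_records: bool = False,
    population_sd: bool = False,
) -> CoverageProfile:
    """Depth per patient and coverage at each requested threshold.

    Mean, median and standard deviation are taken over the whole sample
    universe including zero-depth patients.  The default SD is the sample
    (n-1) estimator; ``population_sd=True`` uses the population form.
    """
    if cohort.n_samples == 0:
        raise ValueError("cohort has an empty sample universe")
    keys = frozenset(
        (l.gene_symbol, l.chromosome, l.start) for l in panel.loci
    )
    depth_map = _patient_depths(keys, cohort, include_silent, count_records)
    arr = np.array(list(depth_map.values()), dtype=float)
    cov = {int(d): float(np.mean(arr >= d)) for d in depths}
    if len(arr) > 1:
        sd = float(np.std(arr, ddof=0 if population_sd else 1))
    else:
        sd = 0.0
    return CoverageProfile(
        depth_by_patient=depth_map,
        coverage_at=cov,
        mean_depth=float(arr.mean()),
        median_depth=float(np.median(arr)),
        sd_depth=sd,
    )


def coverage_curve(
    ranked: Sequence[Locus],
    cohort: Cohort,
    ks: Sequence[int],
    depths: Sequence[int] = (1, 2, 5, 10),
) -> pd.DataFrame:
    """Coverage as a function of panel size k and depth threshold d.

    Equivalent to calling :func:`coverage_profile` on each top-k panel, but
    computed incrementally: walking down the ranking, each locus raises the
    depth of the patients in its patient set by one.  Requires the ranking to
    come from this cohort (loci carry their patient sets).
    """
    ks = list(ks)
    if ks != sorted(ks):
        raise ValueError("ks must be sorted ascending")
    if not ks or ks[-1] > len(ranked):
        raise ValueError("ks empty or exceeding the number of ranked loci")
    sample_index = {s: i for i, s in enumerate(sorted(cohort.samples))}
    depth_arr = np.zeros(len(sample_index), dtype=np.int64)
    rows = []
    k_iter = iter(ks)
    next_k = next(k_iter)
    for i, locus in enumerate(ranked, start=1):
        for s in locus.patient_set:
            depth_arr[sample_index[s]] += 1
        while next_k is not None and i == next_k:
            for d in depths:
                rows.append(
                    {"k": next_k, "d": int(d),
                     "coverage": float(np.mean(depth_arr >= d))}
                )
            next_k = next(k_iter, None)
        if next_k is None:
            break
    return pd.DataFrame(rows, columns=["k", "d", "coverage"])


_TYPE_PRIORITY = (VariantType.SNV, VariantType.INS, VariantType.DEL, VariantType.OTHER)


def _modal_type(locus: Locus) -> VariantType:
    counts = locus.type_counts()
    best = max(counts.values())
    for vt in _TYPE_PRIORITY:  # tie-break SNV > INS > DEL > OTHER
        if counts.get(vt, 0) == best:
            return vt
    return VariantType.OTHER


def panel_composition(
    panel: Panel,
    cohort: Cohort,
    include_silent: bool = False,
    strand_collapse: bool = False,
) -> PanelComposition:
    """Panel make-up: locus variant-type fractions and SNV substitution spectrum.

    Each locus is classified by its modal variant type among the cohort's
    records at that position (ties resolved SNV > INS > DEL).  The spectrum is
    over SNV *records* at panel loci, as 12 "ref>alt" classes or 6
    strand-collapsed classes.  Both sets of fractions sum to 1.  A panel locus
    with no record in the cohort is counted under OTHER with a warning.
    """
    from .hotspots import aggregate_loci

    by_key = {l.key[:3]: l for l in aggregate_loci(cohort, include_silent)}
    type_counts = {vt.value: 0 for vt in _TYPE_PRIORITY}
    subst_counts: dict[str, int] = {}
    n_missing = 0
    for pl in panel.loci:
        locus = by_key.get((pl.gene_symbol, pl.chromosome, pl.start))
        if locus is None:
            n_missing += 1
            type_counts[VariantType.OTHER.value] += 1
            continue
        type_counts[_modal_type(locus).value] += 1
        for cls, c in locus.subst_counts().items():
            cls = collapse_substitution(cls) if strand_collapse else cls
            subst_counts[cls] = subst_counts.get(cls, 0) + c
    if n_missing:
        logger.warning(
            "%d panel locus/loci absent from cohort %r; counted as OTHER",
            n_missing, cohort.name,
        )
    k = panel.k
    type_fractions = {vt: c / k for vt, c in type_counts.items()}
    classes = COLLAPSED_CLASSES if strand_collapse else SUBSTITUTION_CLASSES
    total_snv = sum(subst_counts.values())
    substitution_fractions = {
        cls: (subst_counts.get(cls, 0) / total_snv if total_snv else 0.0)
        for cls in classes
    }
    return PanelComposition(
        type_fractions=type_fractions,
        substitution_fractions=substitution_fractions,
    )


def depth_summary(profile: CoverageProfile) -> tuple[float, float, float]:
    """(mean, median, sd) of per-patient panel depth."""
    return profile.mean_depth, profile.median_depth, profile.sd_depth


def write_panel_tsv(panel: Panel, path: str | Path) -> None:
    rows = [
        {
            "rank": i,
            "label": l.label,
            "gene": l.gene_symbol,
            "chrom": l.chromosome,
            "start": l.start,
            "n_patients": l.n_patients,
            "prevalence": l.prevalence,
        }
        for i, l in enumerate(panel.loci, start=1)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
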