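"""Gene-level driver profiling: alteration matrix, coverage, waterfall order,
pairwise exclusivity/co-occurrence, and protein-position tallies.

The alteration matrix records, per patient and gene, a set of alteration
classes: TRUNCATING (nonsense, frameshift, splice), INFRAME (in-frame
indels), MISSENSE, and from discrete copy-number calls AMP (+2) and DEEP_DEL
(-2).  Silent and non-coding mutation classes never count as alterations;
shallow copy-number calls (±1) are excluded by default, following the
cBioPortal convention.  A patient's *burden* is the number of altered genes
(a gene with both a missense mutation and an amplification counts once).

Pairwise association between genes binarises each cell to altered/not and
runs a two-sided Fisher's exact test on the 2×2 table, with Benjamini–
Hochberg correction across all pairs and a Haldane–Anscombe +0.5 continuity
correction on the odds ratio whenever a cell is empty.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .maf_io import Cohort, VariantClassification, VariantType

logger = logging.getLogger("mutpanel")

__all__ = [
    "AlterationClass",
    "Direction",
    "GeneAlterationMatrix",
    "PairwiseAssociation",
    "DEFAULT_ONCOGENES",
    "DEFAULT_SUPPRESSORS",
    "DEFAULT_DRIVER_GENES",
    "load_gene_lists",
    "build_alteration_matrix",
    "gene_set_coverage",
    "sort_waterfall",
    "pairwise_association",
    "fisher_exact_pvalue",
    "protein_position_tally",
    "ProteinTally",
]


class AlterationClass(Enum):
    AMP = "AMP"
    DEEP_DEL = "DEEP_DEL"
    TRUNCATING = "TRUNCATING"
    INFRAME = "INFRAME"
    MISSENSE = "MISSENSE"


class Direction(Enum):
    CO_OCCURRENCE = "CO_OCCURRENCE"
    MUTUAL_EXCLUSIVITY = "MUTUAL_EXCLUSIVITY"
    NONE = "NONE"


_MUTATION_CLASS_MAP: dict[VariantClassification, AlterationClass] = {
    VariantClassification.MISSENSE: AlterationClass.MISSENSE,
    VariantClassification.NONSENSE: AlterationClass.TRUNCATING,
    VariantClassification.SPLICE: AlterationClass.TRUNCATING,
    VariantClassification.FRAMESHIFT_INS: AlterationClass.TRUNCATING,
    VariantClassification.FRAMESHIFT_DEL: AlterationClass.TRUNCATING,
    VariantClassification.INFRAME_INS: AlterationClass.INFRAME,
    VariantClassification.INFRAME_DEL: AlterationClass.INFRAME,
    # SILENT and OTHER are never alterations
}

# Default driver-gene panel for lung adenocarcinoma: 14 oncogenes and 9
# tumour suppressors frequently altered in the disease.  Fully overridable
# (see load_gene_lists); the statistics below never depend on these names.
DEFAULT_ONCOGENES: tuple[str, ...] = (
    "KRAS", "EGFR", "BRAF", "MET", "PIK3CA", "DDR2", "ERBB2", "ALK",
    "ROS1", "RET", "NRAS", "HRAS", "MAP2K1", "RIT1",
)
DEFAULT_SUPPRESSORS: tuple[str, ...] = (
    "TP53", "CDKN2A", "STK11", "KEAP1", "NF1", "RB1", "SMARCA4", "ATM", "PTEN",
)
DEFAULT_DRIVER_GENES: tuple[str, ...] = DEFAULT_ONCOGENES + DEFAULT_SUPPRESSORS


def load_gene_lists(path: str | Path) -> tuple[list[str], list[str]]:
    """Load a YAML gene-list config with ``oncogenes:`` and ``suppressors:`` keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return list(cfg.get("oncogenes", [])), list(cfg.get("suppressors", []))


@dataclass
class GeneAlterationMatrix:
    """Patient × gene map of alteration-class sets."""

    genes: list[str]
    patients: list[str]
    cells: dict[tuple[str, str], frozenset[AlterationClass]]

    @property
    def burden(self) -> dict[str, int]:
        """Altered-gene count per patient (each altered cell contributes 1)."""
        b = {p: 0 for p in self.patients}
        for (p, _g), classes in self.cells.items():
            if classes:
                b[p] += 1
        return b

    def altered_patients(self, gene: str) -> frozenset[str]:
        return frozenset(
            p for (p, g), classes in self.cells.items() if g == gene and classes
        )

    def to_frame(self) -> pd.DataFrame:
        """Patients × genes table with comma-joined class names ('' = unaltered)."""
        data = {
            g: [
                ",".join(
                    sorted(c.value for c in self.cells.get((p, g), frozenset()))
                )
                for p in self.patients
            ]
            for g in self.genes
        }
        return pd.DataFrame(data, index=self.patients)


@dataclass
class PairwiseAssociation:
    """Fisher-exact association between two genes' alteration statuses."""

    gene_a: str
    gene_b: str
    both: int
    a_only: int
    b_only: int
    neither: int
    log_odds_ratio: float
    p_value: float
    q_value: float
    direction: Direction
    degenerate: bool = False


def build_alteration_matrix(
    cohort: Cohort,
    cna: Optional[Mapping[tuple[str, str], int]] = None,
    genes: Sequence[str] = DEFAULT_DRIVER_GENES,
    include_shallow_cna: bool = False,
) -> GeneAlterationMatrix:
    """Build the patient × gene alteration matrix for a chosen gene set.

    Mutations map NONSENSE/FRAMESHIFT/SPLICE → TRUNCATING, in-frame indels →
    INFRAME, MISSENSE → MISSENSE; SILENT and OTHER are excluded.  CNA calls
    +2 → AMP and -2 → DEEP_DEL; ``include_shallow_cna=True`` also counts ±1.
    A listed gene with no data anywhere keeps an empty column (warning).
    """
    if not genes:
        raise ValueError("gene list is empty")
    gene_list = list(dict.fromkeys(genes))
    gene_set = set(gene_list)
    patients = sorted(cohort.samples)
    cells: dict[tuple[str, str], set[AlterationClass]] = {}

    seen_genes: set[str] = set()
    for r in cohort.records:
        if r.gene_symbol not in gene_set:
            continue
        seen_genes.add(r.gene_symbol)
        cls = _MUTATION_CLASS_MAP.get(r.variant_classification)
        if cls is None:
            continue
        cells.setdefault((r.sample_id, r.gene_symbol), set()).add(cls)

    amp_min, del_max = (1, -1) if include_shallow_cna else (2, -2)
    if cna:
        for (sample, gene), call in cna.items():
            if gene not in gene_set or sample not in cohort.samples:
                continue
            seen_genes.add(gene)
            if call >= amp_min:
                cells.setdefault((sample, gene), set()).add(AlterationClass.AMP)
            elif call <= del_max:
                cells.setdefault((sample, gene), set()).add(AlterationClass.DEEP_DEL)

    for g in gene_set - seen_genes:
        logger.warning("gene %r absent from all mutation and CNA data", g)

    return GeneAlterationMatrix(
        genes=gene_list,
        patients=patients,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


def gene_set_coverage(
    matrix: GeneAlterationMatrix, subset: Sequence[str], min_genes: int = 1
) -> float:
    """Fraction of patients altered in at least ``min_genes`` genes of ``subset``."""
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    sub = set(subset)
    unknown = sub - set(matrix.genes)
    if unknown:
        raise ValueError(f"subset gene(s) not in matrix: {sorted(unknown)}")
    if not matrix.patients:
        raise ValueError("matrix has no patients")
    per_patient = {p: 0 for p in matrix.patients}
    for (p, g), classes in matrix.cells.items():
        if g in sub and classes:
            per_patient[p] += 1
    return sum(1 for c in per_patient.values() if c >= min_genes) / len(matrix.patients)


def sort_waterfall(matrix: GeneAlterationMatrix) -> list[str]:
    """Patients in descending alteration burden; ties by sample id ascending."""
    burden = matrix.burden
    return sorted(matrix.patients, key=lambda p: (-burden[p], p))


def _log_odds(a: int, b: int, c: int, d: int) -> float:
    """Log odds ratio; Haldane–Anscombe +0.5 on every cell when any is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a * d) / (b * c))


def fisher_exact_pvalue(both: int, a_only: int, b_only: int, neither: int) -> float:
    """Two-sided Fisher exact p for one 2×2 table (the test behind
    :func:`pairwise_association`)."""
    _, p = stats.fisher_exact(
        [[both, a_only], [b_only, neither]], alternative="two-sided"
    )
    return min(float(p), 1.0)


def pairwise_association(
    matrix: GeneAlterationMatrix, alpha: float = 0.05
) -> list[PairwiseAssociation]:
    """Fisher's exact test for every unordered gene pair, BH-corrected.

    Each (patient, gene) cell is binarised to altered/not.  Direction is
    CO_OCCURRENCE for OR > 1 and q < alpha, MUTUAL_EXCLUSIVITY for OR < 1 and
    q < alpha, else NONE.  A gene altered in no patient or every patient
    yields an undefined association, reported with p = 1 and flagged
    degenerate.
    """
    if len(matrix.genes) < 2:
        raise ValueError("need at least two genes for pairwise association")
    n = len(matrix.patients)
    altered = {g: matrix.altered_patients(g) for g in matrix.genes}
    raw: list[PairwiseAssociation] = []
    pvals: list[float] = []
    for i, ga in enumerate(matrix.genes):
        for gb in matrix.genes[i + 1:]:
            sa, sb = altered[ga], altered[gb]
            both = len(sa & sb)
            a_only = len(sa) - both
            b_only = len(sb) - both
            neither = n - both - a_only - b_only
            degenerate = len(sa) in (0, n) or len(sb) in (0, n)
            p = 1.0 if degenerate else fisher_exact_pvalue(both, a_only, b_only, neither)
            raw.append(
                PairwiseAssociation(
                    gene_a=ga, gene_b=gb,
                    both=both, a_only=a_only, b_only=b_only, neither=neither,
                    log_odds_ratio=_log_odds(both, a_only, b_only, neither),
                    p_value=p, q_value=1.0,
                    direction=Direction.NONE, degenerate=degenerate,
                )
            )
            pvals.append(p)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for assoc, q in zip(raw, qvals):
        assoc.q_value = float(q)
        if not assoc.degenerate and q < alpha:
            if assoc.log_odds_ratio > 0:
                assoc.direction = Direction.CO_OCCURRENCE
            elif assoc.log_odds_ratio < 0:
                assoc.direction = Direction.MUTUAL_EXCLUSIVITY
    return raw


def association_table(assocs: Iterable[PairwiseAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_a": a.gene_a, "gene_b": a.gene_b,
                "both": a.both, "a_only": a.a_only, "b_only": a.b_only,
                "neither": a.neither, "log_odds_ratio": a.log_odds_ratio,
                "p_value": a.p_value, "q_value": a.q_value,
                "direction": a.direction.value, "degenerate": a.degenerate,
            }
            for a in assocs
        ]
    )


# --- protein-position tallies -------------------------------------------------

# First residue number after "p." in an HGVS-style short protein change:
# p.G12D, p.E746_A750del, p.T790M, p.X125_splice, p.Q61*, p.F507fs ...
_PROTEIN_POS_RE = re.compile(r"^p\.[^0-9]*(\d+)")

_TALLY_CLASS = {
    AlterationClass.MISSENSE: "MISSENSE",
    AlterationClass.TRUNCATING: "TRUNCATING",
    AlterationClass.INFRAME: "INFRAME",
}


@dataclass
class ProteinTally:
    """Per-residue mutation counts for one gene.

    ``counts`` has one row per mutated amino-acid position with MISSENSE /
    TRUNCATING / INFRAME columns; records whose protein-change string cannot
    be parsed (or whose class is silent/non-coding) land in ``unmapped``
    rather than being dropped.  ``snv_position_counts`` restricts to SNV
    records, supporting hotspot-fraction reports such as "x of y SNVs hit
    residue 12".
    """

    gene: str
    counts: pd.DataFrame
    unmapped: int
    snv_position_counts: dict[int, int]
    n_snv_records: int

    def top_position(self) -> Optional[tuple[int, int, float]]:
        """(position, SNV count, fraction of the gene's SNVs) at the busiest residue."""
        if not self.snv_position_counts or self.n_snv_records == 0:
            return None
        pos = max(
            self.snv_position_counts,
            key=lambda p: (self.snv_position_counts[p], -p),
        )
        c = self.snv_position_counts[pos]
        return pos, c, c / self.n_snv_records


def parse_protein_position(protein_change: Optional[str]) -> Optional[int]:
    """Extract the (first) residue number from an HGVS-style protein change."""
    if not protein_change:
        return None
    m = _PROTEIN_POS_RE.match(protein_change.strip())
    return int(m.group(1)) if m else None


def protein_position_tally(
    cohort: Cohort, gene: str, include_silent: bool = False
) -> ProteinTally:
    """Tally mutations of one gene by amino-acid position and class."""
    rows: dict[int, dict[str, int]] = {}
    unmapped = 0
    snv_pos: dict[int, int] = {}
    n_snv = 0
    for r in cohort.records:
        if r.gene_symbol != gene:
            continue
        if not include_silent and r.variant_classification is VariantClassification.SILENT:
            continue
        if r.variant_type is VariantType.SNV:
            n_snv += 1
        cls = _MUTATION_CLASS_MAP.get(r.variant_classification)
        pos = parse_protein_position(r.protein_change)
        if pos is None or cls is None:
            unmapped += 1
            continue
        row = rows.setdefault(pos, {"MISSENSE": 0, "TRUNCATING": 0, "INFRAME": 0})
        row[_TALLY_CLASS[cls]] += 1
        if r.variant_type is VariantType.SNV:
            snv_pos[pos] = snv_pos.get(pos, 0) + 1
    counts = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("position")
        .sort_index()
        .reset_index()
        if rows
        else pd.DataFrame(columns=["position", "MISSENSE", "TRUNCATING", "INFRAME"])
    )
    return ProteinTally(
        gene=gene,
        counts=counts,
        unmapped=unmapped,
        snv_position_counts=snv_pos,
        n_snv_records=n_snv,
    )
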