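"""Synthetic tumour cohorts with known ground truth.

The generator emulates the structure of a somatic-mutation cohort as seen in
a MAF: a small set of true hotspot loci with specified patient prevalences, a
long tail of low-frequency passenger loci, an overdispersed (negative-
binomial) per-patient passenger burden, a configurable base-substitution
spectrum, an indel fraction, and planted pairwise co-occurrence or mutual
exclusivity between designated genes.  Every stage of the pipeline can
therefore be tested against generating parameters without external data.

All randomness flows from a single integer seed; the same spec and seed
produce a byte-identical MAF.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import stats

from .maf_io import (
    Cohort,
    MutationRecord,
    VariantClassification,
    VariantType,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "GroundTruthReport",
    "joint_cell_probabilities",
    "generate_cohort",
    "ground_truth_check",
    "lung_cohort_spec",
    "load_spec",
]

_BASES = "ACGT"
_DEFAULT_WEIGHTS = {
    f"{r}>{a}": 1.0 for r in _BASES for a in _BASES if r != a
}


@dataclass
class SyntheticSpec:
    """Generating parameters for one synthetic cohort.

    ``hotspots`` are (gene, chromosome, start, prevalence) tuples: each
    patient carries each hotspot independently with its prevalence.
    Passenger burden per patient is negative-binomial with the given mean and
    dispersion (smaller dispersion = heavier tail), the loci drawn uniformly
    without replacement from ``passenger_locus_count`` synthetic positions.
    ``exclusivity_pairs`` are (gene_a, gene_b, prevalence_a, prevalence_b,
    odds_ratio) tuples realised by drawing each patient's joint altered
    status from the 2×2 distribution with those margins and odds ratio.
    """

    n_patients: int = 500
    hotspots: list[tuple[str, str, int, float]] = field(default_factory=list)
    passenger_locus_count: int = 2000
    passenger_burden_mean: float = 8.0
    passenger_burden_dispersion: float = 0.5
    substitution_weights: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    indel_fraction: float = 0.0
    exclusivity_pairs: list[tuple[str, str, float, float, float]] = field(
        default_factory=list
    )
    seed: int = 0
    name: str = "synthetic"

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        keys = [(g, c, s) for g, c, s, _p in self.hotspots]
        if len(set(keys)) != len(keys):
            raise ValueError("hotspot keys must be unique")
        for g, c, s, p in self.hotspots:
            if not 0 < p <= 1:
                raise ValueError(f"hotspot prevalence {p} outside (0,1] for {g}")
        if any(w < 0 for w in self.substitution_weights.values()):
            raise ValueError("substitution weights must be non-negative")
        if sum(self.substitution_weights.values()) <= 0:
            raise ValueError("substitution weights must have positive sum")
        for cls in self.substitution_weights:
            r, _, a = cls.partition(">")
            if r not in _BASES or a not in _BASES or r == a:
                raise ValueError(f"bad substitution class {cls!r}")
        if not 0 <= self.indel_fraction < 1:
            raise ValueError("indel_fraction must be in [0,1)")
        if self.passenger_burden_mean < 0 or self.passenger_burden_dispersion <= 0:
            raise ValueError("bad passenger burden parameters")
        hotspot_genes = {g for g, *_ in self.hotspots}
        for ga, gb, pa, pb, orr in self.exclusivity_pairs:
            if orr <= 0:
                raise ValueError("odds_ratio must be > 0")
            if {ga, gb} & hotspot_genes:
                raise ValueError(
                    "exclusivity-pair genes must be disjoint from hotspot genes"
                )
            joint_cell_probabilities(pa, pb, orr)  # raises if infeasible


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    n_patients: int
    hotspots: list[tuple[str, str, int, float]]
    passenger_keys: list[tuple[str, str, int]]
    pairs: list[dict]  # gene_a, gene_b, prevalence_a, prevalence_b, odds_ratio
    seed: int


def joint_cell_probabilities(
    p_a: float, p_b: float, odds_ratio: float
) -> tuple[float, float, float, float]:
    """Cell probabilities (p11, p10, p01, p00) of a 2×2 Bernoulli pair.

    Solves for the joint distribution with margins ``p_a``, ``p_b`` and the
    given odds ratio (the standard quadratic in p11; the root inside the
    Fréchet bounds is taken).  Raises ValueError when no valid distribution
    exists.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("margins must be strictly inside (0,1)")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if odds_ratio == 1.0:
        p11 = p_a * p_b
    else:
        t = 1.0 + (p_a + p_b) * (odds_ratio - 1.0)
        disc = t * t - 4.0 * odds_ratio * (odds_ratio - 1.0) * p_a * p_b
        if disc < 0:
            raise ValueError("no valid 2x2 distribution for these margins and OR")
        p11 = (t - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    cells = (p11, p10, p01, p00)
    if any(c < -1e-12 or c > 1 + 1e-12 for c in cells):
        raise ValueError("no valid 2x2 distribution for these margins and OR")
    return tuple(max(0.0, min(1.0, c)) for c in cells)  # type: ignore[return-value]


def _draw_substitution(rng: np.random.Generator, classes, probs) -> tuple[str, str]:
    idx = rng.choice(len(classes), p=probs)
    ref, _, alt = classes[idx].partition(">")
    return ref, alt


def _snv_record(
    rng, sample, gene, chrom, start, classes, probs
) -> MutationRecord:
    ref, alt = _draw_substitution(rng, classes, probs)
    return MutationRecord(
        sample_id=sample, gene_symbol=gene, chromosome=chrom,
        start=start, end=start, ref_allele=ref, alt_allele=alt,
        variant_type=VariantType.SNV,
        variant_classification=VariantClassification.MISSENSE,
    )


def _indel_record(rng, sample, gene, chrom, start) -> MutationRecord:
    base = _BASES[rng.integers(4)]
    if rng.random() < 0.5:
        return MutationRecord(
            sample_id=sample, gene_symbol=gene, chromosome=chrom,
            start=start, end=start, ref_allele="-", alt_allele=base,
            variant_type=VariantType.INS,
            variant_classification=VariantClassification.FRAMESHIFT_INS,
        )
    return MutationRecord(
        sample_id=sample, gene_symbol=gene, chromosome=chrom,
        start=start, end=start, ref_allele=base, alt_allele="-",
        variant_type=VariantType.DEL,
        variant_classification=VariantClassification.FRAMESHIFT_DEL,
    )


def generate_cohort(
    spec: SyntheticSpec, seed: Optional[int] = None
) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort from the spec.  ``seed`` overrides ``spec.seed``.

    One record at most per (patient, locus): a repeat passenger draw cannot
    occur (sampling without replacement) and hotspot/exclusivity loci are hit
    at most once per patient by construction, matching locus-level detection
    semantics.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_patients
    patients = [f"S{i:05d}" for i in range(n)]

    classes = sorted(spec.substitution_weights)
    w = np.array([spec.substitution_weights[c] for c in classes], dtype=float)
    probs = w / w.sum()

    # passenger locus space: unique synthetic genes, cycling chromosomes
    L = spec.passenger_locus_count
    passenger_keys = [
        (f"PSG{i:05d}", str(1 + i % 22), 100_000_000 + i * 100) for i in range(L)
    ]
    # fixed per-gene loci for exclusivity-pair genes, disjoint from the rest
    pair_genes: list[str] = []
    for ga, gb, *_ in spec.exclusivity_pairs:
        for g in (ga, gb):
            if g not in pair_genes:
                pair_genes.append(g)
    pair_locus = {
        g: ("22", 30_000_000 + i * 10_000) for i, g in enumerate(pair_genes)
    }

    pair_cells = [
        joint_cell_probabilities(pa, pb, orr)
        for _ga, _gb, pa, pb, orr in spec.exclusivity_pairs
    ]

    nb_n = spec.passenger_burden_dispersion
    nb_p = nb_n / (nb_n + spec.passenger_burden_mean) if spec.passenger_burden_mean > 0 else 1.0

    records: list[MutationRecord] = []
    for s in patients:
        for gene, chrom, start, prev in spec.hotspots:
            if rng.random() >= prev:
                continue
            if spec.indel_fraction > 0 and rng.random() < spec.indel_fraction:
                records.append(_indel_record(rng, s, gene, chrom, start))
            else:
                records.append(_snv_record(rng, s, gene, chrom, start, classes, probs))
        for (ga, gb, *_), cells in zip(spec.exclusivity_pairs, pair_cells):
            u = rng.random()
            a_alt = u < cells[0] + cells[1]
            b_alt = u < cells[0] or (cells[0] + cells[1]) <= u < (cells[0] + cells[1] + cells[2])
            for g, alt in ((ga, a_alt), (gb, b_alt)):
                if alt:
                    chrom, start = pair_locus[g]
                    records.append(
                        _snv_record(rng, s, g, chrom, start, classes, probs)
                    )
        if spec.passenger_burden_mean > 0 and L > 0:
            count = int(rng.negative_binomial(nb_n, nb_p))
            count = min(count, L)
            if count:
                idx = rng.choice(L, size=count, replace=False)
                for i in sorted(idx):
                    gene, chrom, start = passenger_keys[i]
                    if spec.indel_fraction > 0 and rng.random() < spec.indel_fraction:
                        records.append(_indel_record(rng, s, gene, chrom, start))
                    else:
                        records.append(
                            _snv_record(rng, s, gene, chrom, start, classes, probs)
                        )

    cohort = Cohort(records=records, samples=frozenset(patients), name=spec.name)
    truth = GroundTruth(
        n_patients=n,
        hotspots=list(spec.hotspots),
        passenger_keys=passenger_keys,
        pairs=[
            {
                "gene_a": ga, "gene_b": gb,
                "prevalence_a": pa, "prevalence_b": pb, "odds_ratio": orr,
            }
            for ga, gb, pa, pb, orr in spec.exclusivity_pairs
        ],
        seed=spec.seed if seed is None else seed,
    )
    return cohort, truth


@dataclass
class GroundTruthReport:
    """Recovered vs planted parameters after generation."""

    hotspot_rows: list[dict]  # gene, chrom, start, planted, observed, ci, within_ci
    pair_rows: list[dict]     # genes, planted OR, observed OR, within_ci
    all_hotspots_within_ci: bool
    all_pairs_within_ci: bool


def ground_truth_check(
    cohort: Cohort, truth: GroundTruth, level: float = 0.99
) -> GroundTruthReport:
    """Compare recovered prevalences and pair odds ratios with the truth.

    Hotspot check: the observed patient count must lie in the central exact
    binomial interval of the planted prevalence at the given level.  Pair
    check: the planted log odds ratio must lie in the Wald interval around
    the observed (Haldane-corrected) log odds ratio.  Both depend only on
    patient-level sets, so the report is invariant to record order.
    """
    n = truth.n_patients
    by_locus: dict[tuple, set[str]] = {}
    by_gene: dict[str, set[str]] = {}
    for r in cohort.records:
        by_locus.setdefault((r.gene_symbol, r.chromosome, r.start), set()).add(
            r.sample_id
        )
        by_gene.setdefault(r.gene_symbol, set()).add(r.sample_id)

    hotspot_rows = []
    for gene, chrom, start, p in truth.hotspots:
        k = len(by_locus.get((gene, chrom, start), ()))
        lo, hi = stats.binom.interval(level, n, p)
        hotspot_rows.append(
            {
                "gene": gene, "chrom": chrom, "start": start,
                "planted_prevalence": p, "observed_count": k,
                "observed_prevalence": k / n,
                "ci_low": int(lo), "ci_high": int(hi),
                "within_ci": lo <= k <= hi,
            }
        )

    z = stats.norm.ppf(0.5 + level / 2)
    pair_rows = []
    for pair in truth.pairs:
        sa = by_gene.get(pair["gene_a"], set())
        sb = by_gene.get(pair["gene_b"], set())
        both = len(sa & sb)
        a_only = len(sa) - both
        b_only = len(sb) - both
        neither = n - both - a_only - b_only
        a, b, c, d = (x + 0.5 for x in (both, a_only, b_only, neither))
        log_or = math.log(a * d / (b * c))
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        planted = math.log(pair["odds_ratio"])
        pair_rows.append(
            {
                **pair,
                "observed_log_or": log_or,
                "planted_log_or": planted,
                "se": se,
                "within_ci": abs(log_or - planted) <= z * se,
            }
        )

    return GroundTruthReport(
        hotspot_rows=hotspot_rows,
        pair_rows=pair_rows,
        all_hotspots_within_ci=all(r["within_ci"] for r in hotspot_rows),
        all_pairs_within_ci=all(r["within_ci"] for r in pair_rows),
    )


def lung_cohort_spec(
    n_patients: int = 519, seed: int = 0, name: str = "synthetic-lung"
) -> SyntheticSpec:
    """Cohort template emulating a lung-adenocarcinoma mutation landscape.

    Ten hotspot loci spanning 3–15% patient prevalence (a KRAS-codon-12-like
    locus at 15% down to a 3% tail), a 20,000-locus passenger space with
    negative-binomial burden (mean 8, dispersion 0.5), a uniform substitution
    spectrum, a 10% indel fraction, and one planted mutually exclusive and
    one co-occurring driver pair.
    """
    hotspots = [
        ("KRAS", "12", 25398285, 0.150),
        ("TP53", "17", 7578406, 0.100),
        ("EGFR", "7", 55259515, 0.080),
        ("IL32", "16", 3119304, 0.052),
        ("RPSA", "3", 24010294, 0.042),
        ("LOC100133050", "10", 99715528, 0.040),
        ("BRAF", "7", 140453136, 0.035),
        ("STK11", "19", 1221320, 0.030),
        ("KEAP1", "19", 10602915, 0.030),
        ("PIK3CA", "3", 178936091, 0.030),
    ]
    return SyntheticSpec(
        n_patients=n_patients,
        hotspots=hotspots,
        passenger_locus_count=20_000,
        passenger_burden_mean=8.0,
        passenger_burden_dispersion=0.5,
        indel_fraction=0.10,
        exclusivity_pairs=[
            ("NF1", "RB1", 0.12, 0.10, 0.25),
            ("ATM", "SMARCA4", 0.08, 0.08, 3.0),
        ],
        seed=seed,
        name=name,
    )


def load_spec(path: str | Path) -> SyntheticSpec:
    """Load a :class:`SyntheticSpec` from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "hotspots" in cfg:
        cfg["hotspots"] = [
            (str(h[0]), str(h[1]), int(h[2]), float(h[3])) for h in cfg["hotspots"]
        ]
    if "exclusivity_pairs" in cfg:
        cfg["exclusivity_pairs"] = [
            (str(p[0]), str(p[1]), float(p[2]), float(p[3]), float(p[4]))
            for p in cfg["exclusivity_pairs"]
        ]
    spec = SyntheticSpec(**cfg)
    spec.validate()
    return spec


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    data = asdict(truth)
    data["passenger_keys"] = [list(k) for k in data["passenger_keys"]]
    data["hotspots"] = [list(h) for h in data["hotspots"]]
    Path(path).write_text(json.dumps(data, indent=1))
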