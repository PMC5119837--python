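"""Reading, validating and writing somatic mutation data.

The exchange format is MAF (Mutation Annotation Format): tab-separated, one
row per called mutation per tumour sample, 1-based inclusive genomic
coordinates.  TCGA-era MAF dialects differ in column capitalisation and
chromosome naming; this module normalises both.  A :class:`Cohort` couples the
mutation records with the *sample universe* — the set of sample barcodes that
defines every denominator downstream.  The universe defaults to the distinct
barcodes seen in the MAF, but an explicit sample list (one barcode per line)
is the correct path whenever mutation-free patients belong to the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger("mutpanel")

__all__ = [
    "VariantType",
    "VariantClassification",
    "MutationRecord",
    "Cohort",
    "MafFormatError",
    "read_maf",
    "write_maf",
    "read_sample_list",
    "write_sample_list",
    "read_cna_table",
]


class MafFormatError(ValueError):
    """Raised when an input file violates the MAF or CNA table contract."""


class VariantType(Enum):
    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"
    OTHER = "OTHER"


class VariantClassification(Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    SPLICE = "SPLICE"
    FRAMESHIFT_INS = "FRAMESHIFT_INS"
    FRAMESHIFT_DEL = "FRAMESHIFT_DEL"
    INFRAME_INS = "INFRAME_INS"
    INFRAME_DEL = "INFRAME_DEL"
    SILENT = "SILENT"
    OTHER = "OTHER"


# TCGA MAF 1.0/2.x Variant_Classification strings -> internal enum.  Strings
# absent from this table classify as OTHER with a logged warning; known
# non-coding categories map to OTHER silently.
CLASSIFICATION_MAP: dict[str, VariantClassification] = {
    "missense_mutation": VariantClassification.MISSENSE,
    "missense": VariantClassification.MISSENSE,
    "nonsense_mutation": VariantClassification.NONSENSE,
    "nonsense": VariantClassification.NONSENSE,
    "splice_site": VariantClassification.SPLICE,
    "splice_site_snp": VariantClassification.SPLICE,
    "splice_region": VariantClassification.SPLICE,
    "frame_shift_ins": VariantClassification.FRAMESHIFT_INS,
    "frame_shift_del": VariantClassification.FRAMESHIFT_DEL,
    "in_frame_ins": VariantClassification.INFRAME_INS,
    "in_frame_del": VariantClassification.INFRAME_DEL,
    "silent": VariantClassification.SILENT,
    "synonymous": VariantClassification.SILENT,
    # non-coding / miscellaneous categories: mapped, but not "alterations"
    "nonstop_mutation": VariantClassification.OTHER,
    "translation_start_site": VariantClassification.OTHER,
    "de_novo_start_inframe": VariantClassification.OTHER,
    "de_novo_start_outofframe": VariantClassification.OTHER,
    "3'utr": VariantClassification.OTHER,
    "5'utr": VariantClassification.OTHER,
    "3'flank": VariantClassification.OTHER,
    "5'flank": VariantClassification.OTHER,
    "intron": VariantClassification.OTHER,
    "igr": VariantClassification.OTHER,
    "rna": VariantClassification.OTHER,
    "targeted_region": VariantClassification.OTHER,
    "other": VariantClassification.OTHER,
}

# Canonical MAF spellings used on write (round-trip safe).
_CLASSIFICATION_WRITE: dict[VariantClassification, str] = {
    VariantClassification.MISSENSE: "Missense_Mutation",
    VariantClassification.NONSENSE: "Nonsense_Mutation",
    VariantClassification.SPLICE: "Splice_Site",
    VariantClassification.FRAMESHIFT_INS: "Frame_Shift_Ins",
    VariantClassification.FRAMESHIFT_DEL: "Frame_Shift_Del",
    VariantClassification.INFRAME_INS: "In_Frame_Ins",
    VariantClassification.INFRAME_DEL: "In_Frame_Del",
    VariantClassification.SILENT: "Silent",
    VariantClassification.OTHER: "Other",
}

_VARIANT_TYPE_MAP: dict[str, VariantType] = {
    "snp": VariantType.SNV,
    "snv": VariantType.SNV,
    "ins": VariantType.INS,
    "del": VariantType.DEL,
}

_VARIANT_TYPE_WRITE: dict[VariantType, str] = {
    VariantType.SNV: "SNP",
    VariantType.INS: "INS",
    VariantType.DEL: "DEL",
    VariantType.OTHER: "OTHER",
}

REQUIRED_MAF_COLUMNS = (
    "hugo_symbol",
    "chromosome",
    "start_position",
    "end_position",
    "reference_allele",
    "tumor_seq_allele2",
    "variant_classification",
    "variant_type",
    "tumor_sample_barcode",
)

_MAF_HEADER = (
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Variant_Type",
    "Tumor_Sample_Barcode",
    "Protein_Change",
)


@dataclass(frozen=True, slots=True)
class MutationRecord:
    """One called somatic mutation in one tumour sample.

    Coordinates are 1-based inclusive (MAF convention).  ``ref_allele`` is
    ``"-"`` for insertions and ``alt_allele`` is ``"-"`` for deletions.
    """

    sample_id: str
    gene_symbol: str
    chromosome: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str
    variant_type: VariantType
    variant_classification: VariantClassification
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.variant_type is VariantType.SNV:
            ok = (
                len(self.ref_allele) == 1
                and len(self.alt_allele) == 1
                and self.ref_allele != "-"
                and self.alt_allele != "-"
                and self.ref_allele != self.alt_allele
            )
            if not ok:
                raise ValueError(
                    f"SNV requires single differing non-'-' bases, got "
                    f"{self.ref_allele}>{self.alt_allele}"
                )
        elif self.variant_type is VariantType.INS and self.ref_allele != "-":
            raise ValueError("INS requires ref_allele '-'")
        elif self.variant_type is VariantType.DEL and self.alt_allele != "-":
            raise ValueError("DEL requires alt_allele '-'")


@dataclass
class Cohort:
    """Mutation records plus the sample universe that defines denominators.

    ``samples`` may include mutation-free patients (they appear in every
    denominator but never in a numerator).
    """

    records: list[MutationRecord]
    samples: frozenset[str]
    name: str = "cohort"

    def __post_init__(self) -> None:
        self.samples = frozenset(self.samples)
        missing = {r.sample_id for r in self.records} - self.samples
        if missing:
            raise ValueError(
                f"records reference samples outside the universe: {sorted(missing)[:5]}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def __len__(self) -> int:
        return len(self.records)


def normalize_chromosome(chrom: str) -> str:
    """Strip 'chr' prefixes and fold numeric sex-chromosome aliases (23→X, 24→Y)."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    return c


def _map_classification(raw: str) -> VariantClassification:
    key = raw.strip().lower()
    if key in CLASSIFICATION_MAP:
        return CLASSIFICATION_MAP[key]
    logger.warning("unmappable Variant_Classification %r -> OTHER", raw)
    return VariantClassification.OTHER


def _infer_variant_type(declared: str, ref: str, alt: str) -> VariantType:
    vt = _VARIANT_TYPE_MAP.get(declared.strip().lower(), VariantType.OTHER)
    # fall back to allele shapes when the declared type contradicts them
    if vt is VariantType.SNV:
        if len(ref) == 1 and len(alt) == 1 and "-" not in (ref, alt) and ref != alt:
            return vt
    elif vt is VariantType.INS:
        if ref == "-":
            return vt
    elif vt is VariantType.DEL:
        if alt == "-":
            return vt
    else:
        return vt
    if ref == "-":
        return VariantType.INS
    if alt == "-":
        return VariantType.DEL
    if len(ref) == 1 and len(alt) == 1 and ref != alt:
        return VariantType.SNV
    return VariantType.OTHER


def read_maf(
    path: str | Path,
    sample_list: Optional[Iterable[str]] = None,
    name: Optional[str] = None,
) -> Cohort:
    """Parse a MAF file into a :class:`Cohort`.

    Parameters
    ----------
    path
        Tab-separated MAF with a header row; lines starting ``#`` are skipped.
        Required columns (case-insensitive): Hugo_Symbol, Chromosome,
        Start_Position, End_Position, Reference_Allele, Tumor_Seq_Allele2,
        Variant_Classification, Variant_Type, Tumor_Sample_Barcode.
    sample_list
        Explicit sample universe.  When given, every barcode in the file must
        belong to it (a barcode outside the list is a hard error); the
        universe may exceed the barcodes present (mutation-free patients).
        When omitted, the universe is the set of distinct barcodes in the file.

    Duplicate rows (identical sample, position span and alleles) are dropped
    with a logged count so that depth statistics are not double-counted.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    colmap = {c.lower(): c for c in df.columns}
    missing = [c for c in REQUIRED_MAF_COLUMNS if c not in colmap]
    if missing:
        raise MafFormatError(
            f"{path}: missing required MAF column(s): {', '.join(missing)}"
        )
    protein_col = colmap.get("protein_change") or colmap.get("hgvsp_short")

    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for row in df.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        get = lambda key: str(row_d[colmap[key]]).strip()
        sample = get("tumor_sample_barcode")
        chrom = normalize_chromosome(get("chromosome"))
        try:
            start = int(get("start_position"))
            end = int(get("end_position"))
        except ValueError as exc:
            raise MafFormatError(f"{path}: non-integer coordinate: {exc}") from exc
        ref = get("reference_allele") or "-"
        alt = get("tumor_seq_allele2") or "-"
        key = (sample, chrom, start, end, ref, alt)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        prot = None
        if protein_col is not None:
            p = str(row_d[protein_col]).strip()
            prot = p or None
        records.append(
            MutationRecord(
                sample_id=sample,
                gene_symbol=get("hugo_symbol"),
                chromosome=chrom,
                start=start,
                end=end,
                ref_allele=ref,
                alt_allele=alt,
                variant_type=_infer_variant_type(get("variant_type"), ref, alt),
                variant_classification=_map_classification(
                    get("variant_classification")
                ),
                protein_change=prot,
            )
        )
    if n_dup:
        logger.info("%s: dropped %d duplicate mutation row(s)", path, n_dup)

    observed = {r.sample_id for r in records}
    if sample_list is not None:
        universe = frozenset(sample_list)
        extra = observed - universe
        if extra:
            raise MafFormatError(
                f"{path}: barcode(s) in MAF absent from the explicit sample list: "
                f"{sorted(extra)[:5]}"
            )
    else:
        universe = frozenset(observed)
    return Cohort(records=records, samples=universe, name=name or path.stem)


def write_maf(
    cohort: Cohort,
    path: str | Path,
    sample_list_path: Optional[str | Path] = None,
) -> None:
    """Write a cohort as a MAF-dialect TSV.

    ``read_maf(write_maf(c))`` reproduces every record field exactly.  The
    sample universe survives the round trip only for samples that carry at
    least one record unless ``sample_list_path`` is also written and passed
    back to :func:`read_maf`.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(_MAF_HEADER) + "\n")
        for r in cohort.records:
            fh.write(
                "\t".join(
                    (
                        r.gene_symbol,
                        r.chromosome,
                        str(r.start),
                        str(r.end),
                        r.ref_allele,
                        r.alt_allele,
                        _CLASSIFICATION_WRITE[r.variant_classification],
                        _VARIANT_TYPE_WRITE[r.variant_type],
                        r.sample_id,
                        r.protein_change or "",
                    )
                )
                + "\n"
            )
    if sample_list_path is not None:
        write_sample_list(cohort.samples, sample_list_path)


def read_sample_list(path: str | Path) -> frozenset[str]:
    """One barcode per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return frozenset(out)


def write_sample_list(samples: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(samples)))


def read_cna_table(path: str | Path) -> dict[tuple[str, str], int]:
    """Read discrete copy-number calls as ``(sample, gene) -> call`` in -2..2.

    Two dialects are auto-detected from the header: long format with
    sample/gene/call columns, or a wide sample × gene matrix (first column =
    sample ids).  -2 is a deep deletion, +2 an amplification; ±1 (shallow)
    calls are retained here but excluded from "alteration" status downstream
    by default.  Empty cells in the wide dialect are skipped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return {}
    lower = [c.lower() for c in df.columns]
    out: dict[tuple[str, str], int] = {}

    def _parse_call(raw: str, row_no: int) -> Optional[int]:
        raw = raw.strip()
        if raw == "" or raw.upper() in ("NA", "NAN"):
            return None
        try:
            val = int(raw)
        except ValueError:
            raise MafFormatError(
                f"{path}: non-integer CNA call {raw!r} at row {row_no}"
            ) from None
        if not -2 <= val <= 2:
            raise MafFormatError(
                f"{path}: CNA call {val} out of range [-2,2] at row {row_no}"
            )
        return val

    if {"sample", "gene"} <= set(lower):
        colmap = {c.lower(): c for c in df.columns}
        call_col = next(
            (colmap[c] for c in ("call", "value", "cna") if c in colmap), None
        )
        if call_col is None:
            raise MafFormatError(f"{path}: long-format CNA table lacks a call column")
        for i, row in enumerate(df.itertuples(index=False), start=2):
            d = dict(zip(df.columns, row))
            val = _parse_call(str(d[call_col]), i)
            if val is not None:
                out[(str(d[colmap["sample"]]).strip(), str(d[colmap["gene"]]).strip())] = val
    else:
        sample_col = df.columns[0]
        genes = list(df.columns[1:])
        for i, row in enumerate(df.itertuples(index=False), start=2):
            d = dict(zip(df.columns, row))
            sample = str(d[sample_col]).strip()
            for g in genes:
                val = _parse_call(str(d[g]), i)
                if val is not None:
                    out[(sample, g)] = val
    return out
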