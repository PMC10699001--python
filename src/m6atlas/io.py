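"""Data model and readers/writers for the formats the pipeline touches.

All tabular formats are plain text: expression and clinical tables are TSV,
copy-number segments use the SEG dialect (1-based inclusive coordinates,
columns Sample/Chromosome/Start/End/Seg.Mean), mutations use a minimal MAF
(Hugo_Symbol / Variant_Classification / Tumor_Sample_Barcode) and gene sets
use GMT.  Gene identifiers are matched case-insensitively and stored
upper-case; missing expression values are a load error, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "SegmentTable",
    "MutationTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "log2_fpkm_transform",
    "read_clinical",
    "write_clinical",
    "read_seg",
    "write_seg",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "NONSYNONYMOUS_CLASSES",
    "MAF_CLASSES",
    "toy_genome",
    "toy_arm_table",
]

SCALE_TAGS = ("raw_fpkm", "log2p1")

# Standard MAF Variant_Classification vocabulary.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Ins",
        "Frame_Shift_Del",
        "In_Frame_Ins",
        "In_Frame_Del",
        "Splice_Site",
        "Translation_Start_Site",
    }
)
MAF_CLASSES = NONSYNONYMOUS_CLASSES | frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a declared scale."""

    values: pd.DataFrame  # index = gene symbols, columns = sample ids
    scale_tag: str = "log2p1"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}")
        self.values.index = self.values.index.astype(str).str.upper()
        self.values.columns = self.values.columns.astype(str)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene symbol: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        if arr.size and arr.min() < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        genes = [g.upper() for g in genes]
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[genes].copy(), self.scale_tag)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival outcome plus optional covariates."""

    data: pd.DataFrame  # index = sample_id; columns os_time, os_event, covariates

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if (self.data["os_time"] < 0).any():
            raise ValueError("os_time must be non-negative")
        if not self.data["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class SegmentTable:
    """Copy-number segments (1-based inclusive bp) with log2 ratios."""

    data: pd.DataFrame  # columns: sample_id, chrom, start, end, log2_ratio

    REQUIRED = ("sample_id", "chrom", "start", "end", "log2_ratio")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.data.columns:
                raise ValueError(f"segment table missing column {col!r}")
        if (self.data["start"] < 1).any() or (self.data["end"] < 1).any():
            raise ValueError("coordinates must be positive (1-based)")
        bad = self.data["start"] > self.data["end"]
        if bad.any():
            row = self.data[bad].iloc[0]
            raise ValueError(
                f"segment start > end: {row['sample_id']} {row['chrom']}:{row['start']}-{row['end']}"
            )

    def lengths(self) -> pd.Series:
        return self.data["end"] - self.data["start"] + 1


@dataclass
class MutationTable:
    """Somatic mutation calls with a derived nonsynonymous flag."""

    data: pd.DataFrame  # columns: sample_id, gene, variant_classification, nonsynonymous

    def __post_init__(self) -> None:
        for col in ("sample_id", "gene", "variant_classification"):
            if col not in self.data.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        if (self.data["sample_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty sample_id in mutation table")
        bad = ~self.data["variant_classification"].isin(MAF_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown variant classification: {self.data.loc[bad, 'variant_classification'].iloc[0]!r}"
            )
        if "nonsynonymous" not in self.data.columns:
            self.data = self.data.assign(
                nonsynonymous=self.data["variant_classification"].isin(NONSYNONYMOUS_CLASSES)
            )


@dataclass
class GeneSetCollection:
    """Named gene sets (upper-cased symbols) with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = {g.upper() for g in genes}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, scale_tag: str = "log2p1") -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene symbols, header = sample ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no genes (empty file)") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"{path}: missing/non-numeric value at gene {gene}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[~df[col].astype(str).str.match(r"^-?[\d.eE+]+$")]
            row = bad.index[0] if len(bad) else df.index[0]
            raise ValueError(f"{path}: non-numeric cell at gene {row}, sample {col}")
    return ExpressionMatrix(df.astype(float), scale_tag=scale_tag)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def log2_fpkm_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(fpkm + 1) transform; refuses to double-transform."""
    if m.scale_tag != "raw_fpkm":
        raise ValueError("matrix is already on the log2p1 scale")
    if (m.values.to_numpy() < 0).any():
        raise ValueError("raw fpkm values must be non-negative")
    return ExpressionMatrix(np.log2(m.values + 1.0), scale_tag="log2p1")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    t.data.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# SEG / MAF
# ---------------------------------------------------------------------------

def read_seg(path: str | Path, genome: Mapping[str, int] | None = None) -> SegmentTable:
    """Read a SEG file (columns Sample/Chromosome/Start/End/Seg.Mean, 1-based inclusive).

    If ``genome`` (chrom -> length) is given, chromosome names are validated
    against it and unknown names are an error.
    """
    df = pd.read_csv(path, sep="\t")
    colmap = {
        "Sample": "sample_id",
        "Chromosome": "chrom",
        "Start": "start",
        "End": "end",
        "Seg.Mean": "log2_ratio",
    }
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file missing columns: {missing}")
    df = df.rename(columns=colmap)[list(colmap.values())]
    df["chrom"] = df["chrom"].astype(str)
    if genome is not None:
        unknown = sorted(set(df["chrom"]) - set(genome))
        if unknown:
            raise ValueError(
                f"unknown chromosomes {unknown}; valid names: {sorted(genome)}"
            )
    return SegmentTable(df)


def write_seg(t: SegmentTable, path: str | Path) -> None:
    out = t.data.rename(
        columns={
            "sample_id": "Sample",
            "chrom": "Chromosome",
            "start": "Start",
            "end": "End",
            "log2_ratio": "Seg.Mean",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_maf(path: str | Path) -> MutationTable:
    """Read a minimal MAF (Hugo_Symbol, Variant_Classification, Tumor_Sample_Barcode)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    colmap = {
        "Hugo_Symbol": "gene",
        "Variant_Classification": "variant_classification",
        "Tumor_Sample_Barcode": "sample_id",
    }
    missing = [c for c in colmap if c not in df.columns]
    if missing:
        raise ValueError(f"MAF file missing columns: {missing}")
    df = df.rename(columns=colmap)
    keep = ["sample_id", "gene", "variant_classification"]
    extra = [c for c in ("ref_allele", "alt_allele") if c in df.columns]
    return MutationTable(df[keep + extra].copy())


def write_maf(t: MutationTable, path: str | Path) -> None:
    out = t.data.rename(
        columns={
            "gene": "Hugo_Symbol",
            "variant_classification": "Variant_Classification",
            "sample_id": "Tumor_Sample_Barcode",
        }
    )
    cols = ["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode"]
    cols += [c for c in ("ref_allele", "alt_allele") if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: gene set {fields[0]!r} has no genes")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise ValueError(f"line {lineno}: duplicate gene set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(c: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in c.names():
            desc = c.descriptions.get(name, "na")
            fh.write("\t".join([name, desc] + sorted(c.sets[name])) + "\n")


# ---------------------------------------------------------------------------
# Toy genome used by the synthetic cohort (and as the default SEG reference)
# ---------------------------------------------------------------------------

def toy_genome(n_chroms: int = 22, chrom_length: int = 100_000_000) -> dict[str, int]:
    """Equal-length toy genome: chr1..chrN, each with the same length."""
    return {f"chr{i}": chrom_length for i in range(1, n_chroms + 1)}


def toy_arm_table(genome: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Arm table for a toy genome: each chromosome split at its midpoint.

    Columns: chrom, arm, start, end (1-based inclusive).
    """
    genome = genome or toy_genome()
    rows = []
    for chrom, length in genome.items():
        mid = length // 2
        rows.append((chrom, f"{chrom}p", 1, mid))
        rows.append((chrom, f"{chrom}q", mid + 1, length))
    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])
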