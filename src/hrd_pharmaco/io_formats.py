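"""Readers and writers for the pipeline's external formats.

Supported formats: GCT 1.2 (text expression matrices), GMT (gene sets),
and TSV clinical / mutation tables. Gene identifiers are opaque,
case-sensitive strings; no symbol or alias resolution is attempted.
Readers reject on type violations rather than silently coercing, and
every writer produces files its paired reader accepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Unit",
    "ExpressionMatrix",
    "GeneSetCollection",
    "MutationTable",
    "FormatError",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_clinical_table",
    "read_mutation_table",
]


class FormatError(ValueError):
    """Malformed input file; message names the offending line where known."""


class Unit(str, Enum):
    counts = "counts"
    log2 = "log2"


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with a unit tag.

    The lingua franca of all pipeline stages. ``unit`` records whether
    values are raw counts (non-negative) or log2-scale intensities.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: Unit = Unit.counts

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if isinstance(self.unit, str):
            self.unit = Unit(self.unit)
        if self.unit is Unit.counts and np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("counts matrix contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, unit: Unit | str = Unit.counts) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            unit=unit,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows], self.unit)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:10]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols], self.unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, non-empty member lists."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has an empty member list")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class MutationTable:
    """Minimal mutation records: sample, gene, variant classification and an
    optional pre-annotated deleterious flag (NaN when not annotated)."""

    records: pd.DataFrame  # columns: sample_id, gene, variant_classification, deleterious

    def __post_init__(self):
        required = ["sample_id", "gene", "variant_classification", "deleterious"]
        for col in required:
            if col not in self.records.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        if (self.records["sample_id"].astype(str).str.len() == 0).any():
            raise ValueError("empty sample_id in mutation table")
        if (self.records["gene"].astype(str).str.len() == 0).any():
            raise ValueError("empty gene in mutation table")


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def read_gct(path) -> ExpressionMatrix:
    """Parse a GCT 1.2 text matrix.

    Tolerates DOS line endings. Errors name the offending line number.
    The Description column is ignored on read.
    """
    path = Path(path)
    with open(path, "r", newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected GCT version header '#1.2'")
    if len(lines) < 3:
        raise FormatError(f"{path}: line 2: missing dimension line")
    dims = lines[1].split("\t")
    try:
        n_rows, n_cols = int(dims[0]), int(dims[1])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: line 2: malformed dimension line {lines[1]!r}") from exc
    header = lines[2].split("\t")
    if len(header) != n_cols + 2:
        raise FormatError(
            f"{path}: line 3: expected {n_cols + 2} header fields (Name, Description, "
            f"{n_cols} samples), found {len(header)}"
        )
    sample_ids = header[2:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: line 3: duplicate sample ids")
    body = [ln for ln in lines[3:] if ln != ""]
    if len(body) != n_rows:
        raise FormatError(
            f"{path}: line 2: dimension line declares {n_rows} rows but {len(body)} present"
        )
    gene_ids: list[str] = []
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, ln in enumerate(body):
        fields = ln.split("\t")
        if len(fields) != n_cols + 2:
            raise FormatError(
                f"{path}: line {i + 4}: expected {n_cols + 2} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        try:
            values[i] = [float(v) for v in fields[2:]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {i + 4}: non-numeric value") from exc
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"{path}: duplicate gene ids in body")
    unit = Unit.counts if (values >= 0).all() and np.allclose(values, np.round(values)) else Unit.log2
    return ExpressionMatrix(gene_ids, sample_ids, values, unit)


def write_gct(matrix: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\tna\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file. Duplicate members within a set are
    deduplicated (order-preserving) with a logged warning; duplicate set
    names are an error."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    "(name, description, members...)"
                )
            name, desc = fields[0], fields[1]
            members = [m for m in fields[2:] if m != ""]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning(
                    "%s: set %r: %d duplicate member(s) removed",
                    path, name, len(members) - len(deduped),
                )
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write(name + "\t" + desc + "\t" + "\t".join(members) + "\n")


# ---------------------------------------------------------------------------
# Clinical / mutation TSV
# ---------------------------------------------------------------------------

def read_clinical_table(path, required_columns=("sample_id",)) -> pd.DataFrame:
    """TSV clinical table with header. Missing values ('', 'NA', 'NaN')
    propagate as NaN, never as silent zeros. Unknown extra columns are kept
    with a warning; a missing required column is an error naming it."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""], keep_default_na=True)
    for col in required_columns:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} absent")
    extra = [c for c in df.columns if c not in required_columns]
    if extra:
        logger.warning("%s: extra columns ignored by schema: %s", path, extra)
    return df


def read_mutation_table(path) -> MutationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA", "NaN", ""], keep_default_na=True)
    for col in ("sample_id", "gene", "variant_classification"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} absent")
    if "deleterious" not in df.columns:
        df["deleterious"] = np.nan
    df["sample_id"] = df["sample_id"].astype(str)
    df["gene"] = df["gene"].astype(str)
    return MutationTable(records=df[["sample_id", "gene", "variant_classification", "deleterious"]])
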