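"""Readers and writers for the pipeline's tabular formats.

All quantitative tables are TSV with mandatory headers.  Gene models are
read from BED6 (0-based half-open, native) or GTF (1-based closed,
converted on read); internally every coordinate is 0-based half-open.
CpG positions are 1-based positions of the cytosine on the annotated
strand; plus- and minus-strand CpGs are never merged into dinucleotide
units.

Each reader validates its schema and invariants and raises a typed error
(:mod:`spinasym.errors`) naming the offending column or row.  Writers emit
a canonical column order and deterministic sort, so read -> write -> read
is an identity.
"""

from __future__ import annotations

import io
import os
from typing import Iterable, Mapping

import pandas as pd
import pyranges as pr

from .config import SIDES, normalize_stage
from .errors import (
    CoordinateError,
    PairingError,
    RowValueError,
    SchemaError,
    UniquenessError,
)

EXPRESSION_COLUMNS = ["feature_id", "sample_id", "stage", "side", "fpkm"]
MIRNA_COLUMNS = [
    "mirna_id", "sample_id", "stage", "side",
    "read_count", "transcript_length", "library_size",
]
CPG_COLUMNS = ["chrom", "pos", "strand", "sample_id", "stage", "side",
               "coverage", "methylated"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
TARGET_COLUMNS = ["mirna_id", "gene_id", "probability"]

_SORT_KEYS: Mapping[str, list[str]] = {
    "expression": ["stage", "feature_id", "sample_id", "side"],
    "mirna": ["stage", "mirna_id", "sample_id", "side"],
    "cpg": ["stage", "chrom", "pos", "strand", "sample_id", "side"],
    "genes": ["chrom", "start", "gene_id"],
    "targets": ["mirna_id", "gene_id"],
}


def _read_tsv(source, required: Iterable[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return df


def _numeric(df: pd.DataFrame, column: str, kind: str = "float") -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = converted.isna()
    if bad.any():
        row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise RowValueError(f"column {column!r}: non-numeric value at line {row}")
    if kind == "int":
        if not (converted % 1 == 0).all():
            row = int((converted % 1 != 0).idxmax()) + 2
            raise RowValueError(f"column {column!r}: non-integer value at line {row}")
        converted = converted.astype(int)
    else:
        converted = converted.astype(float)
    return converted


def _require(df: pd.DataFrame, mask: pd.Series, message: str) -> None:
    """Raise RowValueError at the first row where ``mask`` is False."""
    bad = ~mask
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise RowValueError(f"{message} at line {row}")


def _check_unique(df: pd.DataFrame, key: list[str], label: str) -> None:
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup.idxmax(), key].tolist()
        raise UniquenessError(f"duplicate {label} key {first!r}")


def _check_sides(df: pd.DataFrame) -> None:
    bad = ~df["side"].isin(SIDES)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise RowValueError(f"column 'side': expected left/right at line {row}")


def _check_paired(df: pd.DataFrame, key: list[str]) -> None:
    sides = df.groupby(key, sort=False)["side"].nunique()
    unpaired = sides[sides < 2]
    if len(unpaired):
        raise PairingError(f"missing side for {key} = {list(unpaired.index[:5])}")


def read_expression(source) -> pd.DataFrame:
    """Read and validate a gene-level FPKM table.

    Requires both sides present for every (feature, sample) pair; FPKM must
    be non-negative.  Stage labels are normalized to PC weeks.
    """
    df = _read_tsv(source, EXPRESSION_COLUMNS)[EXPRESSION_COLUMNS].copy()
    df["stage"] = df["stage"].map(normalize_stage)
    _check_sides(df)
    df["fpkm"] = _numeric(df, "fpkm")
    _require(df, df["fpkm"] >= 0, "column 'fpkm': negative value")
    _check_unique(df, ["feature_id", "sample_id", "side"], "expression")
    _check_paired(df, ["feature_id", "sample_id"])
    return df.reset_index(drop=True)


def read_mirna_counts(source) -> pd.DataFrame:
    """Read and validate a miRNA raw-count table with lengths and library sizes."""
    df = _read_tsv(source, MIRNA_COLUMNS)[MIRNA_COLUMNS].copy()
    df["stage"] = df["stage"].map(normalize_stage)
    _check_sides(df)
    for col in ("read_count", "transcript_length", "library_size"):
        df[col] = _numeric(df, col, kind="int")
    _require(df, df["read_count"] >= 0, "column 'read_count': negative value")
    _require(df, df["transcript_length"] > 0, "column 'transcript_length': non-positive value")
    _require(df, df["library_size"] > 0, "column 'library_size': non-positive value")
    _require(df, df["read_count"] <= df["library_size"],
             "read_count exceeds library_size")
    _check_unique(df, ["mirna_id", "sample_id", "side"], "miRNA count")
    _check_paired(df, ["mirna_id", "sample_id"])
    return df.reset_index(drop=True)


def read_cpg_calls(source) -> pd.DataFrame:
    """Read and validate per-CpG methylation calls.

    ``pos`` is the 1-based position of the CpG cytosine on ``strand``;
    ``methylated`` must not exceed ``coverage``.
    """
    df = _read_tsv(source, CPG_COLUMNS)[CPG_COLUMNS].copy()
    df["stage"] = df["stage"].map(normalize_stage)
    _check_sides(df)
    _require(df, df["strand"].isin(["+", "-"]), "column 'strand': expected +/-")
    df["pos"] = _numeric(df, "pos", kind="int")
    df["coverage"] = _numeric(df, "coverage", kind="int")
    df["methylated"] = _numeric(df, "methylated", kind="int")
    _require(df, df["pos"] >= 1, "column 'pos': positions are 1-based")
    _require(df, df["coverage"] > 0, "column 'coverage': non-positive value")
    _require(df, df["methylated"] >= 0, "column 'methylated': negative value")
    _require(df, df["methylated"] <= df["coverage"],
             "methylated exceeds coverage")
    _check_unique(df, ["chrom", "pos", "strand", "sample_id", "side"], "CpG")
    return df.reset_index(drop=True)


def read_targets(source) -> pd.DataFrame:
    """Read a miRNA -> gene target table with interaction probabilities."""
    df = _read_tsv(source, TARGET_COLUMNS)[TARGET_COLUMNS].copy()
    df["probability"] = _numeric(df, "probability")
    _require(df, (df["probability"] >= 0) & (df["probability"] <= 1),
             "column 'probability': outside [0, 1]")
    _check_unique(df, ["mirna_id", "gene_id"], "target")
    return df.reset_index(drop=True)


def read_gene_models(source, dialect: str = "bed") -> pd.DataFrame:
    """Read gene models from BED6 or GTF into 0-based half-open coordinates.

    Parameters
    ----------
    source
        Path or file-like object.
    dialect
        ``"bed"`` (0-based half-open, stored as-is) or ``"gtf"`` (1-based
        closed, start shifted down by one on read).
    """
    if dialect == "bed":
        df = pd.read_csv(
            source, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "gene_id", "score", "strand"],
            dtype={"chrom": str, "gene_id": str, "strand": str},
        )
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    elif dialect == "gtf":
        if hasattr(source, "read"):
            text = source.read()
            tmp = io.StringIO(text) if isinstance(text, str) else io.BytesIO(text)
            df = _gtf_frame_from_buffer(tmp)
        else:
            df = _gtf_frame_from_path(os.fspath(source))
    else:
        raise SchemaError(f"unknown gene-model dialect {dialect!r}")
    df["start"] = _numeric(df, "start", kind="int")
    df["end"] = _numeric(df, "end", kind="int")
    _require(df, df["strand"].isin(["+", "-"]), "column 'strand': expected +/-")
    bad = df["start"] >= df["end"]
    if bad.any():
        gene = df.loc[bad.idxmax(), "gene_id"]
        raise CoordinateError(f"empty or inverted interval for gene {gene!r}")
    _check_unique(df, ["gene_id"], "gene model")
    return df[GENE_COLUMNS].reset_index(drop=True)


def _gtf_frame_from_path(path: str) -> pd.DataFrame:
    # pyranges converts GTF's 1-based closed Start to 0-based on read
    gr = pr.read_gtf(path)
    df = gr.df
    df = df[df["Feature"].isin(["gene", "transcript"]) | (df["Feature"] == "gene")]
    genes = df[df["Feature"] == "gene"] if (df["Feature"] == "gene").any() else df
    out = genes.rename(columns={
        "Chromosome": "chrom", "Start": "start", "End": "end",
        "Strand": "strand", "gene_id": "gene_id",
    })
    if "gene_id" not in out.columns:
        raise SchemaError("GTF records lack a gene_id attribute")
    return out[["gene_id", "chrom", "start", "end", "strand"]].astype(
        {"chrom": str, "gene_id": str, "strand": str}
    )


def _gtf_frame_from_buffer(buf) -> pd.DataFrame:
    import tempfile

    data = buf.read()
    if isinstance(data, bytes):
        data = data.decode()
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(data)
        path = fh.name
    try:
        return _gtf_frame_from_path(path)
    finally:
        os.unlink(path)


def write_table(df: pd.DataFrame, destination, kind: str) -> None:
    """Write a validated table as TSV in canonical column order and sort."""
    columns = {
        "expression": EXPRESSION_COLUMNS,
        "mirna": MIRNA_COLUMNS,
        "cpg": CPG_COLUMNS,
        "genes": GENE_COLUMNS,
        "targets": TARGET_COLUMNS,
    }[kind]
    out = df[columns].sort_values(_SORT_KEYS[kind], kind="mergesort")
    out.to_csv(destination, sep="\t", index=False)


def write_gene_models_bed(df: pd.DataFrame, destination) -> None:
    """Write gene models as BED6 (coordinates already 0-based half-open)."""
    out = df.sort_values(_SORT_KEYS["genes"], kind="mergesort")
    bed = pd.DataFrame({
        "chrom": out["chrom"], "start": out["start"], "end": out["end"],
        "name": out["gene_id"], "score": ".", "strand": out["strand"],
    })
    bed.to_csv(destination, sep="\t", index=False, header=False)


READERS = {
    "expression": read_expression,
    "mirna": read_mirna_counts,
    "cpg": read_cpg_calls,
    "targets": read_targets,
    "genes": read_gene_models,
}
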