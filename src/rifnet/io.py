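"""Readers and writers for the plain-text exchange formats.

* Expression matrix: TSV, first column header ``feature_id``, remaining
  columns one per sample.
* Sample metadata: TSV with columns ``sample_id``, ``group`` and an
  optional ``imf`` column.
* Annotation: 7-column BED-like TSV (chrom, start, end, feature_id,
  score, strand, biotype) with BED coordinates (0-based half-open) on
  disk; converted to 1-based inclusive in memory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .data import (ConsistencyError, ExpressionMatrix, FormatError,
                   validate_annotation, validate_phenotype)

_BED_COLUMNS = ["chrom", "start", "end", "feature_id", "score", "strand", "biotype"]


def read_expression_matrix(path: str | Path,
                           metadata_path: str | Path) -> ExpressionMatrix:
    """Read an FPKM matrix and its sample metadata from TSV files."""
    # round_trip parsing so write -> read is bit-exact for 17-digit output
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     float_precision="round_trip")
    if df.columns[0] != "feature_id":
        raise FormatError(
            f"{path}: first column must be 'feature_id', got {df.columns[0]!r}"
        )
    df = df.set_index("feature_id")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc

    meta = read_metadata(metadata_path)
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise ConsistencyError(
            f"samples in matrix absent from metadata: {list(missing)}"
        )
    return ExpressionMatrix(values, meta["group"].reindex(values.columns))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise FormatError(f"{path}: metadata missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in metadata")
    return meta.set_index("sample_id")


def write_metadata(groups: pd.Series, path: str | Path,
                   imf: pd.Series | None = None) -> None:
    out = pd.DataFrame({"group": groups})
    if imf is not None:
        out["imf"] = imf.reindex(groups.index)
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_phenotype(path: str | Path,
                   matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    meta = read_metadata(path)
    if "imf" not in meta.columns:
        raise FormatError(f"{path}: metadata has no 'imf' column")
    return validate_phenotype(meta[["imf", "group"]], matrix)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a 7-column BED-like file into 1-based inclusive coordinates."""
    try:
        bed = pd.read_csv(path, sep="\t", header=None, names=_BED_COLUMNS,
                          dtype={"chrom": str, "feature_id": str})
    except pd.errors.EmptyDataError:
        bed = pd.DataFrame(columns=_BED_COLUMNS)
    if len(bed) == 0:
        ann = bed.set_index("feature_id")[["chrom", "start", "end", "strand",
                                           "biotype"]]
        return validate_annotation(ann)
    if (bed["start"] >= bed["end"]).any():
        bad = bed.loc[bed["start"] >= bed["end"], "feature_id"].iloc[0]
        raise FormatError(f"{path}: start >= end for feature {bad!r}")
    ann = pd.DataFrame({
        "chrom": bed["chrom"].to_numpy(),
        "start": bed["start"].to_numpy() + 1,  # BED 0-based -> 1-based
        "end": bed["end"].to_numpy(),
        "strand": bed["strand"].to_numpy(),
        "biotype": bed["biotype"].to_numpy(),
    }, index=pd.Index(bed["feature_id"], name="feature_id"))
    if ann.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids in annotation")
    return validate_annotation(ann)


def write_annotation(ann: pd.DataFrame, path: str | Path) -> None:
    """Write internal 1-based inclusive annotation as BED-like TSV."""
    validate_annotation(ann)
    bed = pd.DataFrame({
        "chrom": ann["chrom"],
        "start": ann["start"] - 1,
        "end": ann["end"],
        "feature_id": ann.index,
        "score": np.zeros(len(ann), dtype=int),
        "strand": ann["strand"],
        "biotype": ann["biotype"],
    })
    bed.to_csv(path, sep="\t", header=False, index=False)
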