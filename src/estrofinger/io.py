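"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
expression matrix
    TSV, first column ``probe_id``, one column per sample, values written
    with 6 decimal places.
sample sheet
    CSV with columns sample_id, group, dose_mg_ml (empty where no numeric
    dose applies), replicate.
probe annotation
    TSV with columns probe_id, gene_symbol, description.
external fold changes
    two-column TSV (probe_id, log2_fc), used by the concordance filter.
signature
    TSV with columns probe_id, gene_symbol, direction, reference_fc.
classification
    TSV, one row per probe with category, fold changes and dose trend.
dendrograms
    Newick via :meth:`ClusterTree.to_newick`.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .matrix import ContrastTable, ExpressionMatrix, ProbeAnnotation
from .signature import Signature

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6f"


def write_expression_matrix(matrix: ExpressionMatrix, matrix_path, sample_sheet_path) -> None:
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(matrix_path, sep="\t", float_format=_FLOAT_FMT)
    sheet = matrix.samples.reset_index()
    sheet.columns = ["sample_id", "group", "dose_mg_ml", "replicate"]
    sheet.to_csv(sample_sheet_path, index=False)
    logger.info("wrote %d x %d matrix to %s", *matrix.values.shape, matrix_path)


def read_expression_matrix(matrix_path, sample_sheet_path) -> ExpressionMatrix:
    """Read a TSV expression matrix and its CSV sample sheet.

    Sample order is taken from the sample sheet. Raises
    :class:`ValidationError` when matrix and sheet disagree on sample ids or
    probes are duplicated, and :class:`ParseError` (with row/column context)
    for malformed cells or an empty file.
    """
    matrix_path, sample_sheet_path = Path(matrix_path), Path(sample_sheet_path)
    try:
        raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{matrix_path}: empty expression matrix file") from None
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ParseError(f"{matrix_path}: expression matrix has no data rows/columns")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{matrix_path}: non-numeric value at row {row!r}, column {col!r}")
        values[col] = converted

    samples = read_sample_sheet(sample_sheet_path)
    return ExpressionMatrix(values, samples)


def read_sample_sheet(path) -> pd.DataFrame:
    path = Path(path)
    try:
        sheet = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty sample sheet") from None
    required = ["sample_id", "group", "dose_mg_ml", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"duplicate sample ids in sheet: {dups}")
    sheet["dose_mg_ml"] = pd.to_numeric(sheet["dose_mg_ml"], errors="coerce")
    sheet["replicate"] = sheet["replicate"].astype(int)
    return sheet.set_index("sample_id")


def write_annotation(annotation: ProbeAnnotation, path) -> None:
    out = annotation.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> ProbeAnnotation:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty annotation file") from None
    return ProbeAnnotation(table)


def write_contrast_table(table: ContrastTable, path) -> None:
    out = table.table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_contrast_table(path, name: str | None = None) -> ContrastTable:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty contrast table") from None
    return ContrastTable(name or path.stem, table)


def read_external_logfc(path) -> dict[str, float]:
    """Read a two-column TSV (probe_id, log2_fc) into a probe -> log2 fc map.

    Duplicate probes raise a :class:`ValidationError`; an empty file yields
    an empty map with a logged warning.
    """
    path = Path(path)
    result: dict[str, float] = {}
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(row)}")
            pid = row[0].strip()
            if lineno == 1 and pid.lower() in {"probe_id", "probe"}:
                continue  # optional header
            if pid in result:
                raise ValidationError(f"{path}: duplicate probe id {pid!r}")
            try:
                result[pid] = float(row[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric log2 fc {row[1]!r}") from None
    if not result:
        logger.warning("%s: empty external fold-change file", path)
    return result


def write_external_logfc(profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tlog2_fc\n")
        for pid, lfc in profile.items():
            fh.write(f"{pid}\t{lfc:.6f}\n")


def write_signature(sig: Signature, path) -> None:
    out = sig.probes[["gene_symbol", "direction", "reference_fc"]].copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_signature(path, contrast_name: str = "") -> Signature:
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty signature file") from None
    table["reference_fc"] = pd.to_numeric(table["reference_fc"])
    return Signature(table[["direction", "reference_fc", "gene_symbol"]], contrast_name)


def write_classification(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick if newick.endswith("\n") else newick + "\n")


def write_truth(truth_table: pd.DataFrame, path) -> None:
    out = truth_table.copy()
    out.index.name = "probe_id"
    out.to_csv(path, sep="\t", float_format="%.6f")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
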