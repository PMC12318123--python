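"""Delimited-table readers and writers for matrices, metadata and QC reports.

Matrices are features x samples: the header row holds sample ids and the
first column holds feature ids.  Missing entries are read from a
configurable token set (default ``NA``, ``NaN`` and the empty cell) and
always written back as ``NA``.  The delimiter is auto-detected between tab
and comma unless given explicitly.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import DataValidationError, OmicsMatrix, QCReport, SampleMeta

__all__ = ["read_matrix", "write_matrix", "read_meta", "write_outputs"]

DEFAULT_MISSING_TOKENS = ("NA", "NaN", "")


def _sniff_delimiter(path: str | Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path: str | Path,
    missing_tokens: Sequence[str] = DEFAULT_MISSING_TOKENS,
    delimiter: Optional[str] = None,
    transpose: bool = False,
) -> OmicsMatrix:
    """Read a feature x sample matrix from a TSV/CSV file.

    Cells equal to one of ``missing_tokens`` (or empty) become missing; all
    other cells must parse as finite reals.  ``transpose=True`` accepts a
    sample x feature file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise DataValidationError("no features: file is empty")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, index_col=0,
        na_values=list(missing_tokens), keep_default_na=False,
        skip_blank_lines=True, float_precision="round_trip",
    )
    if df.shape[0] == 0:
        raise DataValidationError("no features")
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str),
                       dtype=np.float64)
    for col in df.columns:
        series = df[col]
        if series.dtype == object:  # locate the offending cell
            converted = pd.to_numeric(series, errors="coerce")
            bad = converted.isna() & series.notna()
            if not bad.any():
                out[col] = converted.to_numpy(dtype=np.float64)
                continue
            row = series.index[bad][0]
            raise DataValidationError(
                f"non-numeric value {series[bad].iloc[0]!r} at "
                f"feature {row!r}, sample {col!r}"
            )
        out[col] = series.to_numpy(dtype=np.float64)
    if transpose:
        out = out.T
    return OmicsMatrix(out)


def write_matrix(matrix: OmicsMatrix, path: str | Path,
                 delimiter: str = "\t") -> None:
    """Write a matrix with missing values encoded as ``NA``."""
    matrix.data.to_csv(path, sep=delimiter, na_rep="NA")


def read_meta(
    path: str | Path,
    batch_col: str = "batch",
    label_col: Optional[str] = None,
    covariate_cols: Sequence[str] = (),
    reference_col: Optional[str] = None,
    delimiter: Optional[str] = None,
    sample_col: Optional[str] = None,
) -> SampleMeta:
    """Read a sample-metadata table (one row per sample).

    The sample-id column is the first column unless ``sample_col`` names
    another one.  ``reference_col`` holds truthy/falsy flags (1/0,
    true/false); when absent, no sample is a reference.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     na_values=["NA", "NaN", ""])
    if sample_col is None:
        sample_col = df.columns[0]
    df = df.set_index(sample_col)
    df.index = df.index.astype(str)
    is_reference = None
    if reference_col is not None:
        if reference_col not in df.columns:
            raise DataValidationError(f"reference column {reference_col!r} not found")
        truthy = {"1", "true", "yes", "t", "y"}
        is_reference = df[reference_col].astype(str).str.strip().str.lower().isin(truthy)
    return SampleMeta(
        table=df,
        batch_col=batch_col,
        label_col=label_col,
        covariate_cols=tuple(covariate_cols),
        is_reference=is_reference,
    )


def write_outputs(matrix: OmicsMatrix, report: QCReport,
                  out_dir: str | Path, delimiter: str = "\t") -> None:
    """Write the corrected matrix and the QC report into ``out_dir``.

    Row and column order of the matrix are written exactly as held, which
    the tree engine keeps identical to the original user input.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_matrix(matrix, out_dir / "corrected.tsv", delimiter=delimiter)
    (out_dir / "qc_report.json").write_text(report.to_json() + "\n",
                                            encoding="utf-8")
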