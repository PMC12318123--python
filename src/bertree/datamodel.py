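"""Core data containers: omics matrices, sample annotations and QC reports.

The central object is :class:`OmicsMatrix`, a feature x sample table of
log-scale intensities in which ``NaN`` marks a missing measurement.
:class:`SampleMeta` carries per-sample batch of origin, an optional
biological label, optional categorical covariates and a reference flag.
:class:`QCReport` summarises a correction run (value bookkeeping, average
silhouette widths before/after, elapsed time).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataValidationError",
    "OmicsMatrix",
    "SampleMeta",
    "QCReport",
]


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise DataValidationError(f"duplicate {what} ids: {dups[:5]}")


@dataclass
class OmicsMatrix:
    """A feature x sample numeric matrix with missing entries allowed.

    Parameters
    ----------
    data
        DataFrame with features as rows and samples as columns.  Values are
        coerced to float64; ``NaN`` encodes a missing measurement.  Infinite
        values are rejected.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise TypeError("OmicsMatrix.data must be a pandas DataFrame")
        if self.data.shape[0] == 0:
            raise DataValidationError("no features")
        df = self.data.astype(np.float64, copy=False)
        _check_unique(df.index, "feature")
        _check_unique(df.columns, "sample")
        vals = df.to_numpy()
        if np.isinf(vals).any():
            raise DataValidationError("matrix contains infinite values")
        self.data = df

    # -- convenience accessors -------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray,
        feature_ids: Sequence[str],
        sample_ids: Sequence[str],
    ) -> "OmicsMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=np.float64),
                                index=pd.Index(feature_ids),
                                columns=pd.Index(sample_ids)))

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        """Underlying float64 array (features x samples)."""
        return self.data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a value is observed (non-missing)."""
        return ~np.isnan(self.values)

    @property
    def n_numeric(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.data.copy())

    def with_values(self, values: np.ndarray) -> "OmicsMatrix":
        """Same ids, new value array (shape must match)."""
        if values.shape != self.data.shape:
            raise DataValidationError("replacement values have wrong shape")
        return OmicsMatrix(pd.DataFrame(values, index=self.data.index,
                                        columns=self.data.columns))


@dataclass
class SampleMeta:
    """Per-sample annotations: batch, optional label, covariates, references.

    ``table`` is indexed by sample id and holds the columns named by
    ``batch_col``/``label_col``/``covariate_cols``/``reference flag``.
    Batch and covariate values must be known for every sample.
    """

    table: pd.DataFrame
    batch_col: str = "batch"
    label_col: Optional[str] = None
    covariate_cols: tuple[str, ...] = ()
    is_reference: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            raise TypeError("SampleMeta.table must be a pandas DataFrame")
        _check_unique(self.table.index, "sample")
        self.covariate_cols = tuple(self.covariate_cols)
        for col in (self.batch_col, self.label_col, *self.covariate_cols):
            if col is not None and col not in self.table.columns:
                raise DataValidationError(f"metadata column {col!r} not found")
        batch = self.table[self.batch_col]
        if batch.isna().any():
            bad = self.table.index[batch.isna()].tolist()
            raise DataValidationError(f"batch missing for samples {bad[:5]}")
        for col in self.covariate_cols:
            if self.table[col].isna().any():
                bad = self.table.index[self.table[col].isna()].tolist()
                raise DataValidationError(
                    f"covariate {col!r} missing for samples {bad[:5]}: "
                    "covariates must be known for every sample"
                )
        if self.is_reference is None:
            self.is_reference = pd.Series(False, index=self.table.index)
        else:
            self.is_reference = pd.Series(self.is_reference).reindex(
                self.table.index).fillna(False).astype(bool)

    # -- accessors --------------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def batches(self) -> pd.Series:
        return self.table[self.batch_col].astype(str)

    @property
    def labels(self) -> Optional[pd.Series]:
        if self.label_col is None:
            return None
        return self.table[self.label_col]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table[list(self.covariate_cols)]

    def batch_order(self) -> list[str]:
        """Batch ids in order of first appearance."""
        return list(dict.fromkeys(self.batches))

    def validate_against(self, matrix: OmicsMatrix) -> "SampleMeta":
        """Check the sample-id sets match; return a copy in matrix order."""
        meta_ids = set(self.sample_ids)
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            only_m = sorted(mat_ids - meta_ids)[:5]
            only_t = sorted(meta_ids - mat_ids)[:5]
            raise DataValidationError(
                "sample ids of matrix and metadata differ "
                f"(matrix-only: {only_m}, metadata-only: {only_t})"
            )
        return SampleMeta(
            table=self.table.reindex(matrix.sample_ids),
            batch_col=self.batch_col,
            label_col=self.label_col,
            covariate_cols=self.covariate_cols,
            is_reference=self.is_reference.reindex(matrix.sample_ids),
        )

    def subset(self, sample_ids: Iterable[str]) -> "SampleMeta":
        ids = pd.Index(sample_ids)
        return SampleMeta(
            table=self.table.loc[ids],
            batch_col=self.batch_col,
            label_col=self.label_col,
            covariate_cols=self.covariate_cols,
            is_reference=self.is_reference.loc[ids],
        )


@dataclass
class QCReport:
    """Bookkeeping and quality metrics for one correction run.

    Numeric values are only ever lost during pre-processing (singleton
    removal), so ``n_numeric_out == n_numeric_in - n_numeric_removed_preprocessing``.
    ASW fields lie in [-1, 1]; label fields are None when no biological
    label was provided.
    """

    n_numeric_in: int
    n_numeric_removed_preprocessing: int
    n_numeric_out: int
    asw_batch_raw: Optional[float] = None
    asw_batch_corrected: Optional[float] = None
    asw_label_raw: Optional[float] = None
    asw_label_corrected: Optional[float] = None
    elapsed_seconds: float = 0.0
    n_pairwise_steps: int = 0

    def __post_init__(self) -> None:
        if self.n_numeric_out != self.n_numeric_in - self.n_numeric_removed_preprocessing:
            raise DataValidationError(
                "value conservation violated: "
                f"{self.n_numeric_out} != {self.n_numeric_in} - "
                f"{self.n_numeric_removed_preprocessing}"
            )
        for name in ("asw_batch_raw", "asw_batch_corrected",
                     "asw_label_raw", "asw_label_corrected"):
            v = getattr(self, name)
            if v is not None and not (-1.0 <= v <= 1.0):
                raise DataValidationError(f"{name}={v} outside [-1, 1]")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(dataclasses.asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "QCReport":
        return cls(**json.loads(text))
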