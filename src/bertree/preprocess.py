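"""Pre-processing: singleton removal and per-pair feature eligibility.

The pairwise correction back-ends require at least two numeric values per
feature within each batch they touch.  This module enforces the relaxed
completeness condition — every (feature, batch) cell of the design holds
either no numeric values or at least two — by deleting singleton values,
and classifies features per batch pair into CORRECT / PROPAGATE / ABSENT.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .datamodel import DataValidationError, OmicsMatrix, SampleMeta

__all__ = ["Eligibility", "EligibilityTable", "remove_singletons",
           "classify_features", "batch_observation_counts"]


class Eligibility(Enum):
    CORRECT = "correct"
    PROPAGATE_A = "propagate_a"
    PROPAGATE_B = "propagate_b"
    ABSENT = "absent"


@dataclass
class EligibilityTable:
    """Per-feature eligibility for one (batchA, batchB) correction step."""

    batch_a: str
    batch_b: str
    categories: np.ndarray  # of Eligibility, aligned to feature order
    feature_ids: pd.Index

    @property
    def correct_mask(self) -> np.ndarray:
        return self.categories == Eligibility.CORRECT

    def counts(self) -> dict[Eligibility, int]:
        return {e: int((self.categories == e).sum()) for e in Eligibility}


def batch_observation_counts(matrix: OmicsMatrix, meta: SampleMeta) -> pd.DataFrame:
    """Numeric-value counts per feature (rows) and batch (columns)."""
    obs = pd.DataFrame(matrix.mask.astype(np.int64),
                       index=matrix.feature_ids, columns=matrix.sample_ids)
    return obs.T.groupby(meta.batches, sort=False).sum().T


def remove_singletons(matrix: OmicsMatrix, meta: SampleMeta
                      ) -> tuple[OmicsMatrix, int]:
    """Delete every numeric value that is alone in its (feature, batch) cell.

    Returns the cleaned matrix and the number of values removed.  After this
    step every (feature, batch) cell holds 0 or >=2 numeric values, and the
    operation is idempotent.
    """
    meta = meta.validate_against(matrix)
    values = matrix.values.copy()
    obs = ~np.isnan(values)
    batches = meta.batches.to_numpy()
    removed = 0
    for b in meta.batch_order():
        cols = batches == b
        counts = obs[:, cols].sum(axis=1)
        single = counts == 1
        if single.any():
            removed += int(single.sum())
            block = values[np.ix_(single, cols)]
            block[:] = np.nan
            values[np.ix_(single, cols)] = block
    return matrix.with_values(values), removed


def classify_features(matrix: OmicsMatrix, meta: SampleMeta,
                      batch_a: str, batch_b: str) -> EligibilityTable:
    """Assign each feature CORRECT / PROPAGATE_A / PROPAGATE_B / ABSENT.

    CORRECT means >=2 numeric values in both batches; PROPAGATE_A/B means
    only batch A (resp. B) carries data for the feature; ABSENT means
    neither does.  Assumes singletons were already removed.
    """
    if batch_a == batch_b:
        raise DataValidationError("batchA and batchB must differ")
    meta = meta.validate_against(matrix)
    batches = meta.batches.to_numpy()
    obs = matrix.mask
    n_a = obs[:, batches == batch_a].sum(axis=1)
    n_b = obs[:, batches == batch_b].sum(axis=1)
    return _classify_from_counts(n_a, n_b, batch_a, batch_b, matrix.feature_ids)


def _classify_from_counts(n_a: np.ndarray, n_b: np.ndarray,
                          batch_a: str, batch_b: str,
                          feature_ids: pd.Index) -> EligibilityTable:
    cats = np.empty(len(n_a), dtype=object)
    cats[:] = Eligibility.ABSENT
    cats[(n_a >= 2) & (n_b >= 2)] = Eligibility.CORRECT
    cats[(n_a >= 2) & (n_b == 0)] = Eligibility.PROPAGATE_A
    cats[(n_a == 0) & (n_b >= 2)] = Eligibility.PROPAGATE_B
    stray = ((n_a == 1) | (n_b == 1))
    if stray.any():
        raise DataValidationError(
            "encountered a (feature, batch) cell with exactly one numeric "
            "value; run remove_singletons first"
        )
    return EligibilityTable(batch_a=batch_a, batch_b=batch_b,
                            categories=cats, feature_ids=feature_ids)
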