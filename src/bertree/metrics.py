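"""Average silhouette width (ASW) with respect to batch or biological label.

ASW is the mean over samples of ``(b_i - a_i) / max(a_i, b_i)`` where
``a_i`` is the mean distance of sample *i* to its own group and ``b_i`` the
mean distance to the nearest other group; it lies in [-1, 1].  Computed
with respect to the batch of origin a *lower* score indicates better
integration; with respect to the biological label a *higher* score
indicates better-preserved signal.

Distances are Euclidean over the features observed in both samples,
rescaled by ``sqrt(F_total / F_shared)`` so that pairs with different
amounts of shared data remain comparable.  Members of singleton groups
contribute silhouette 0 (standard convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples
from sklearn.metrics.pairwise import euclidean_distances, nan_euclidean_distances

from .datamodel import DataValidationError, OmicsMatrix

__all__ = ["SilhouetteResult", "pairwise_distances", "asw"]


@dataclass
class SilhouetteResult:
    asw: float
    n_samples_used: int
    grouping: str

    def __post_init__(self) -> None:
        if not (-1.0 <= self.asw <= 1.0):
            raise DataValidationError(f"ASW {self.asw} outside [-1, 1]")


def pairwise_distances(matrix: OmicsMatrix) -> np.ndarray:
    """Sample x sample distance matrix, tolerant of missing values.

    Raises if any sample pair shares zero observed features, since no
    distance is defined for it.
    """
    if matrix.shape[1] < 2:
        raise DataValidationError("need at least 2 samples")
    X = matrix.values.T  # samples x features
    if not np.isnan(X).any():
        D = euclidean_distances(X)
    else:
        D = nan_euclidean_distances(X)
        if np.isnan(D).any():
            i, j = np.argwhere(np.isnan(D))[0]
            raise DataValidationError(
                "sample pair shares zero observed features: "
                f"({matrix.sample_ids[i]!r}, {matrix.sample_ids[j]!r})")
    np.fill_diagonal(D, 0.0)
    return D


def asw(matrix: OmicsMatrix, grouping: pd.Series | np.ndarray,
        grouping_name: str = "group") -> SilhouetteResult:
    """Average silhouette width of samples under a categorical grouping.

    Samples with a missing group value are excluded (and not counted in
    ``n_samples_used``).  At least two groups are required.
    """
    g = pd.Series(np.asarray(grouping, dtype=object),
                  index=matrix.sample_ids)
    keep = g.notna().to_numpy()
    if keep.sum() < 2:
        raise DataValidationError("fewer than 2 samples with group labels")
    sub = OmicsMatrix(matrix.data.loc[:, keep]) if not keep.all() else matrix
    labels = g[keep].astype(str).to_numpy()
    n_groups = len(np.unique(labels))
    if n_groups < 2:
        raise DataValidationError("ASW requires at least 2 groups")
    if n_groups >= len(labels):
        raise DataValidationError(
            "ASW undefined when every sample forms its own group")
    D = pairwise_distances(sub)
    sil = silhouette_samples(D, labels, metric="precomputed")
    return SilhouetteResult(asw=float(np.mean(sil)),
                            n_samples_used=int(keep.sum()),
                            grouping=grouping_name)
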