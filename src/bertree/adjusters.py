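"""Pairwise batch-effect correction back-ends.

Three correctors operate on a pair of batches of one feature x sample
matrix, all tolerant of missing values and aware of categorical covariates:

* :func:`correct_pair_combat` — parametric empirical-Bayes location/scale
  adjustment.  Per feature the model is ``y = alpha + X beta + gamma_i +
  delta_i * eps`` with additive (gamma) and multiplicative (delta) batch
  effects; per-batch estimates are shrunk toward a normal prior (gamma) and
  an inverse-gamma prior (delta) via the iterative posterior solution, then
  the data are back-transformed with batch effects removed.
* :func:`correct_pair_linear` — per-feature ordinary least squares of the
  observed values on an intercept, a sum-to-zero batch indicator and
  dummy-coded covariates; only the fitted batch term is subtracted.
* :func:`correct_pair_references` — the batch shift is estimated by OLS on
  user-flagged reference samples only and then subtracted from *all*
  samples of each batch.

Missingness is handled by computing every per-feature sum/moment over
observed entries only, with per-feature per-batch observed counts taking
the place of the sample size in each estimator.  Features without at least
two numeric values in both batches (or, for the reference mode, two numeric
reference values per batch) are propagated through unchanged.

:func:`correct_onestep_linear` applies the same linear model in a single
step across arbitrarily many batches; it serves as the whole-matrix
comparator for the hierarchical procedure.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import DataValidationError, OmicsMatrix, SampleMeta

__all__ = [
    "DesignError",
    "correct_pair_combat",
    "correct_pair_linear",
    "correct_pair_references",
    "correct_onestep_linear",
    "correct_pair_values",
]

logger = logging.getLogger("bertree")

EB_CONV = 1e-6          # absolute change threshold for the EB iteration
EB_MAX_ITER = 100


class DesignError(DataValidationError):
    """Raised when a design matrix is rank-deficient (confounded)."""


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def covariate_dummies(cov: Optional[pd.DataFrame]) -> tuple[np.ndarray, list[str]]:
    """Dummy-code categorical covariates, dropping one reference level each.

    Returns an (n_samples, k) float array (k may be 0) and the column names
    ``"col=level"``.  Level order is lexicographic, so the coding is
    deterministic.
    """
    if cov is None or cov.shape[1] == 0:
        n = 0 if cov is None else len(cov)
        return np.empty((n, 0)), []
    dummies = pd.get_dummies(cov.astype(str), prefix_sep="=", drop_first=True)
    return dummies.to_numpy(dtype=np.float64), list(dummies.columns)


def _check_full_rank(X: np.ndarray, names: Sequence[str], context: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify columns that do not add rank beyond the others
    offenders = []
    for j in range(X.shape[1]):
        keep = [k for k in range(X.shape[1]) if k != j]
        if np.linalg.matrix_rank(X[:, keep]) == rank:
            offenders.append(names[j])
    raise DesignError(
        f"{context}: design matrix is rank-deficient "
        f"(rank {rank} < {X.shape[1]} columns); "
        f"collinear columns: {offenders}"
    )


def _patterned_lstsq(Y: np.ndarray, X: np.ndarray, names: Sequence[str],
                     context: str) -> np.ndarray:
    """Per-feature OLS of Y (features x samples) on X (samples x p).

    Missing entries of ``Y`` drop the corresponding rows of ``X`` for that
    feature.  Features sharing a missingness pattern are solved together.
    """
    obs = ~np.isnan(Y)
    coefs = np.empty((Y.shape[0], X.shape[1]))
    patterns, inverse = np.unique(obs, axis=0, return_inverse=True)
    for k in range(patterns.shape[0]):
        pat = patterns[k]
        rows = inverse == k
        Xs = X[pat]
        _check_full_rank(Xs, names, context)
        sol, *_ = np.linalg.lstsq(Xs, Y[np.ix_(rows, pat)].T, rcond=None)
        coefs[rows] = sol.T
    return coefs


def _nanmean_sides(Y: np.ndarray, in_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore"):
        mu_a = np.nanmean(Y[:, ~in_b], axis=1)
        mu_b = np.nanmean(Y[:, in_b], axis=1)
    return mu_a, mu_b


# ---------------------------------------------------------------------------
# array-level correctors (operate on CORRECT-eligible rows only)
# ---------------------------------------------------------------------------

def _linear_core(Y: np.ndarray, in_b: np.ndarray,
                 X_cov: np.ndarray, cov_names: list[str]) -> np.ndarray:
    """OLS on intercept + sum-to-zero batch (+1 for A, -1 for B) + covariates;
    subtract the fitted batch term only."""
    x_batch = np.where(in_b, -1.0, 1.0)
    if X_cov.shape[1] == 0:
        mu_a, mu_b = _nanmean_sides(Y, in_b)
        coef_batch = (mu_a - mu_b) / 2.0
    else:
        X = np.column_stack([np.ones(Y.shape[1]), x_batch, X_cov])
        names = ["intercept", "batch"] + cov_names
        coefs = _patterned_lstsq(Y, X, names, "linear correction")
        coef_batch = coefs[:, 1]
    return Y - coef_batch[:, None] * x_batch[None, :]


def _combat_core(Y: np.ndarray, in_b: np.ndarray,
                 X_cov: np.ndarray, cov_names: list[str],
                 conv: float = EB_CONV, max_iter: int = EB_MAX_ITER) -> np.ndarray:
    """Parametric empirical-Bayes location/scale correction for one pair."""
    obs = ~np.isnan(Y)
    n_a = obs[:, ~in_b].sum(axis=1).astype(float)
    n_b = obs[:, in_b].sum(axis=1).astype(float)
    n_tot = n_a + n_b

    # 1. per-feature fit: batch means (one-hot) + covariates
    if X_cov.shape[1] == 0:
        mu_a, mu_b = _nanmean_sides(Y, in_b)
        fitted = np.where(in_b[None, :], mu_b[:, None], mu_a[:, None])
        cov_contrib = np.zeros_like(Y)
    else:
        X = np.column_stack([(~in_b).astype(float), in_b.astype(float), X_cov])
        names = ["batchA", "batchB"] + cov_names
        coefs = _patterned_lstsq(Y, X, names, "ComBat correction")
        fitted = coefs @ X.T
        cov_contrib = coefs[:, 2:] @ X_cov.T
        mu_a, mu_b = coefs[:, 0], coefs[:, 1]

    # 2. standardization: observed-count-weighted grand mean, pooled variance
    grand = (n_a * mu_a + n_b * mu_b) / n_tot
    stand_mean = grand[:, None] + cov_contrib
    resid = np.where(obs, Y - fitted, np.nan)
    with np.errstate(invalid="ignore"):
        var_pooled = np.nansum(resid ** 2, axis=1) / n_tot
    scale = np.sqrt(var_pooled)
    degenerate = var_pooled <= 0
    scale[degenerate] = 1.0  # rows are restored verbatim below
    Z = (Y - stand_mean) / scale[:, None]

    # 3. per-batch location/scale estimates on the standardized data
    out = np.array(Y, copy=True)
    dev = np.empty_like(Y)
    for side, cols, n_i in ((0, ~in_b, n_a), (1, in_b, n_b)):
        Zi = Z[:, cols]
        with np.errstate(invalid="ignore"):
            g_hat = np.nanmean(Zi, axis=1)
            d_hat = np.nanvar(Zi, axis=1, ddof=1)
        g_star, d_star = _eb_shrink(Zi, g_hat, d_hat, n_i, conv, max_iter)
        d_star = np.maximum(d_star, np.finfo(float).tiny)
        dev[:, cols] = (Zi - g_star[:, None]) / np.sqrt(d_star)[:, None]

    adjusted = dev * scale[:, None] + stand_mean
    keep = ~degenerate
    out[keep] = adjusted[keep]
    if degenerate.any():
        logger.warning("%d feature(s) with zero pooled variance propagated "
                       "unchanged", int(degenerate.sum()))
    return out


def _eb_shrink(Zi: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
               n_i: np.ndarray, conv: float, max_iter: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Iterative posterior solution for one batch across all features.

    Hyper-priors are estimated by method of moments across features:
    a normal prior for the location and an inverse-gamma prior
    (moment-matched shape/scale) for the squared scale.
    """
    n_feat = len(g_hat)
    if n_feat < 2:
        return g_hat, d_hat
    g_bar = float(np.mean(g_hat))
    t2 = float(np.var(g_hat, ddof=1))
    m = float(np.mean(d_hat))
    s2 = float(np.var(d_hat, ddof=1))
    if s2 <= 0 or t2 <= 0:
        logger.warning("degenerate empirical-Bayes prior moments; "
                       "shrinkage skipped for this batch")
        return g_hat, d_hat
    a_prior = (2 * s2 + m ** 2) / s2
    b_prior = (m * s2 + m ** 3) / s2

    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n_i * t2 * g_hat + d_old * g_bar) / (n_i * t2 + d_old)
        with np.errstate(invalid="ignore"):
            sum2 = np.nansum((Zi - g_new[:, None]) ** 2, axis=1)
        d_new = (b_prior + 0.5 * sum2) / (n_i / 2.0 + a_prior - 1.0)
        change = max(np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old)))
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def _references_core(Y: np.ndarray, in_b: np.ndarray, ref: np.ndarray,
                     X_cov: np.ndarray, cov_names: list[str]) -> np.ndarray:
    """Estimate the batch shift on reference samples only; shift everyone."""
    x_batch = np.where(in_b, -1.0, 1.0)
    Y_ref = Y[:, ref]
    if X_cov.shape[1] == 0:
        mu_a, mu_b = _nanmean_sides(Y_ref, in_b[ref])
        coef_batch = (mu_a - mu_b) / 2.0
    else:
        X = np.column_stack([np.ones(int(ref.sum())), x_batch[ref], X_cov[ref]])
        names = ["intercept", "batch"] + cov_names
        coefs = _patterned_lstsq(Y_ref, X, names, "reference correction")
        coef_batch = coefs[:, 1]
    return Y - coef_batch[:, None] * x_batch[None, :]


# ---------------------------------------------------------------------------
# dispatch with eligibility
# ---------------------------------------------------------------------------

def correct_pair_values(
    values: np.ndarray,
    in_b: np.ndarray,
    method: str,
    cov: Optional[pd.DataFrame] = None,
    ref_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Correct one batch pair at array level.

    ``values`` is features x samples with NaN missingness, ``in_b`` flags
    the samples of the second batch.  Features are screened for
    eligibility; ineligible ones are returned bit-identical.  When
    ``ref_mask`` is given the reference-based estimator is used and
    ``method`` is ignored for the shift estimation (it is always linear).
    """
    values = np.asarray(values, dtype=np.float64)
    in_b = np.asarray(in_b, dtype=bool)
    obs = ~np.isnan(values)
    n_a = obs[:, ~in_b].sum(axis=1)
    n_b = obs[:, in_b].sum(axis=1)
    if ((n_a == 1) | (n_b == 1)).any():
        raise DataValidationError(
            "pair contains (feature, batch) cells with exactly one numeric "
            "value; run remove_singletons first")
    eligible = (n_a >= 2) & (n_b >= 2)

    X_cov, cov_names = covariate_dummies(cov)

    if ref_mask is not None:
        ref_mask = np.asarray(ref_mask, dtype=bool)
        if not ref_mask[~in_b].any() or not ref_mask[in_b].any():
            raise DataValidationError(
                "reference-based correction requires at least one reference "
                "sample in every batch")
        ref_a = obs[:, ref_mask & ~in_b].sum(axis=1)
        ref_b = obs[:, ref_mask & in_b].sum(axis=1)
        eligible &= (ref_a >= 2) & (ref_b >= 2)
        core = lambda Y: _references_core(Y, in_b, ref_mask, X_cov, cov_names)
    elif method == "limma":
        core = lambda Y: _linear_core(Y, in_b, X_cov, cov_names)
    elif method == "combat":
        core = lambda Y: _combat_core(Y, in_b, X_cov, cov_names)
    else:
        raise ValueError(f"unknown method {method!r}; choose 'combat' or 'limma'")

    out = np.array(values, copy=True)
    if eligible.any():
        out[eligible] = core(values[eligible])
    # correction must never create or destroy numeric values
    out[~obs] = np.nan
    return out


# ---------------------------------------------------------------------------
# public OmicsMatrix-level API
# ---------------------------------------------------------------------------

def _pair_context(matrix: OmicsMatrix, meta: SampleMeta):
    meta = meta.validate_against(matrix)
    order = meta.batch_order()
    if len(order) != 2:
        raise DataValidationError(
            f"pairwise correction requires exactly 2 batches, got {len(order)}")
    in_b = (meta.batches == order[1]).to_numpy()
    return meta, in_b


def correct_pair_combat(matrix: OmicsMatrix, meta: SampleMeta,
                        covariate_cols: Sequence[str] = ()) -> OmicsMatrix:
    """Empirical-Bayes location/scale correction of a two-batch matrix."""
    meta, in_b = _pair_context(matrix, meta)
    cov = meta.table[list(covariate_cols)] if covariate_cols else None
    out = correct_pair_values(matrix.values, in_b, "combat", cov=cov)
    return matrix.with_values(out)


def correct_pair_linear(matrix: OmicsMatrix, meta: SampleMeta,
                        covariate_cols: Sequence[str] = ()) -> OmicsMatrix:
    """Linear-model correction of a two-batch matrix (batch term removed)."""
    meta, in_b = _pair_context(matrix, meta)
    cov = meta.table[list(covariate_cols)] if covariate_cols else None
    out = correct_pair_values(matrix.values, in_b, "limma", cov=cov)
    return matrix.with_values(out)


def correct_pair_references(matrix: OmicsMatrix, meta: SampleMeta,
                            covariate_cols: Sequence[str] = ()) -> OmicsMatrix:
    """Reference-anchored correction: shift estimated on flagged references."""
    meta, in_b = _pair_context(matrix, meta)
    cov = meta.table[list(covariate_cols)] if covariate_cols else None
    out = correct_pair_values(matrix.values, in_b, "limma", cov=cov,
                              ref_mask=meta.is_reference.to_numpy())
    return matrix.with_values(out)


def correct_onestep_linear(matrix: OmicsMatrix, meta: SampleMeta,
                           covariate_cols: Sequence[str] = ()) -> OmicsMatrix:
    """Single whole-matrix linear correction over all batches at once.

    With sum-to-zero batch coding and no covariates this centres every
    feature's batch means on their unweighted average.  Serves as the
    one-step comparator for the hierarchical tree.
    """
    meta = meta.validate_against(matrix)
    order = meta.batch_order()
    if len(order) < 2:
        raise DataValidationError("need at least 2 batches")
    Y = matrix.values
    batches = meta.batches.to_numpy()
    if not covariate_cols:
        batch_means = np.empty((Y.shape[0], len(order)))
        with np.errstate(invalid="ignore"):
            for k, b in enumerate(order):
                batch_means[:, k] = np.nanmean(Y[:, batches == b], axis=1)
            center = np.nanmean(batch_means, axis=1)
        shift = np.zeros_like(Y)
        for k, b in enumerate(order):
            cols = batches == b
            shift[:, cols] = (batch_means[:, k] - center)[:, None]
        out = Y - shift
        out[np.isnan(Y)] = np.nan
        return matrix.with_values(out)
    # general path: sum-coded batch columns + covariate dummies
    n = Y.shape[1]
    B = len(order)
    Xb = np.zeros((n, B - 1))
    for k, b in enumerate(order[:-1]):
        Xb[batches == b, k] = 1.0
    Xb[batches == order[-1], :] = -1.0
    X_cov, cov_names = covariate_dummies(meta.table[list(covariate_cols)])
    X = np.column_stack([np.ones(n), Xb, X_cov])
    names = (["intercept"] + [f"batch[{b}]" for b in order[:-1]] + cov_names)
    coefs = _patterned_lstsq(Y, X, names, "one-step linear correction")
    batch_term = coefs[:, 1:B] @ Xb.T
    out = Y - batch_term
    out[np.isnan(Y)] = np.nan
    return matrix.with_values(out)
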