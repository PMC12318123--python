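"""Synthetic multi-batch omics data under the generalized location/scale model.

Each value is drawn as

    y_ijf = alpha_f + X beta_f + gamma_if + delta_if * eps_ijf

for feature f, batch i, sample j: a feature baseline ``alpha_f`` (standard
normal), a condition effect ``X beta_f`` with dummy-coded condition
membership and standard-normal coefficients, an additive batch effect
``gamma_if`` (standard normal), and noise scaled by a multiplicative batch
effect ``delta_if`` drawn from an inverse-gamma distribution (default
shape 5, scale 2, i.e. mean scale/(shape-1) = 0.5).

Missingness is feature-wise MCAR per batch: a random subset of features is
set fully missing within a batch, never partially — matching the
acquisition pattern of isobaric-labelling proteomics, where a peptide is
either quantified across a whole batch or not at all.  Class imbalance and
reference designation are configurable per batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataValidationError, OmicsMatrix, SampleMeta

__all__ = ["SimConfig", "GroundTruth", "generate", "apply_feature_mcar",
           "make_imbalanced_pair"]

logger = logging.getLogger("bertree")


@dataclass
class SimConfig:
    """Parameters of the generative model and study design."""

    n_features: int = 6000
    n_batches: int = 20
    samples_per_batch: int = 10
    n_conditions: int = 2
    class_ratio: Optional[Sequence[float]] = None  # default: balanced
    randomize_minority: bool = True
    missing_fraction: float = 0.0
    ig_shape: float = 5.0
    ig_scale: float = 2.0
    n_references_per_batch: int = 0
    null_batch_effects: bool = False  # gamma = 0, delta = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise DataValidationError("n_batches must be >= 2")
        if self.samples_per_batch < 2:
            raise DataValidationError("samples_per_batch must be >= 2")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise DataValidationError("missing_fraction must be in [0, 1)")
        if self.n_conditions < 1:
            raise DataValidationError("n_conditions must be >= 1")
        if self.class_ratio is not None:
            r = tuple(float(x) for x in self.class_ratio)
            if len(r) != self.n_conditions:
                raise DataValidationError(
                    "class_ratio must have one entry per condition")
            if abs(sum(r) - 1.0) > 1e-9 or min(r) < 0:
                raise DataValidationError("class ratios must be >= 0 and sum to 1")
            self.class_ratio = r
        if self.n_references_per_batch < 0:
            raise DataValidationError("n_references_per_batch must be >= 0")


@dataclass
class GroundTruth:
    """All parameters drawn for one simulated dataset."""

    alpha: np.ndarray                 # (F,)
    beta: np.ndarray                  # (F, n_conditions - 1)
    gamma: np.ndarray                 # (B, F)
    delta: np.ndarray                 # (B, F)
    conditions: pd.Series = field(repr=False)  # per sample
    batch_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "conditions": self.conditions.to_dict(),
            "batch_ids": list(self.batch_ids),
        }


def _condition_counts(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-batch condition counts, with optional random minority placement."""
    ratio = cfg.class_ratio or tuple([1.0 / cfg.n_conditions] * cfg.n_conditions)
    base = np.array([int(round(r * cfg.samples_per_batch)) for r in ratio])
    # fix rounding drift on the largest class
    base[int(np.argmax(base))] += cfg.samples_per_batch - base.sum()
    if base.min() < 0:
        raise DataValidationError("class ratio incompatible with batch size")
    counts = np.empty((cfg.n_batches, cfg.n_conditions), dtype=int)
    for i in range(cfg.n_batches):
        if cfg.randomize_minority:
            counts[i] = rng.permutation(base)
        else:
            counts[i] = base
    return counts


def generate(config: SimConfig) -> tuple[OmicsMatrix, SampleMeta, GroundTruth]:
    """Draw one dataset from the generative model; deterministic given seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    F, B, n = cfg.n_features, cfg.n_batches, cfg.samples_per_batch

    alpha = rng.standard_normal(F)
    beta = rng.standard_normal((F, max(cfg.n_conditions - 1, 0)))
    if cfg.null_batch_effects:
        gamma = np.zeros((B, F))
        delta = np.ones((B, F))
    else:
        gamma = rng.standard_normal((B, F))
        delta = stats.invgamma.rvs(a=cfg.ig_shape, scale=cfg.ig_scale,
                                   size=(B, F), random_state=rng)

    counts = _condition_counts(cfg, rng)
    batch_ids = tuple(f"B{i + 1:02d}" for i in range(B))
    sample_ids, batches, conditions, is_ref = [], [], [], []
    values = np.empty((F, B * n))
    col = 0
    for i, b in enumerate(batch_ids):
        conds: list[int] = []
        for c in range(cfg.n_conditions):
            conds.extend([c] * counts[i, c])
        # reference designation: cycle over conditions so references are
        # spread across classes (one per condition for 2 refs, 2 conditions)
        ref_flags = [False] * n
        if cfg.n_references_per_batch:
            remaining = {c: [k for k, cc in enumerate(conds) if cc == c]
                         for c in range(cfg.n_conditions)}
            c = 0
            assigned = 0
            guard = 0
            while assigned < cfg.n_references_per_batch:
                if remaining[c % cfg.n_conditions]:
                    k = remaining[c % cfg.n_conditions].pop(0)
                    ref_flags[k] = True
                    assigned += 1
                    guard = 0
                else:
                    guard += 1
                    if guard > cfg.n_conditions:
                        raise DataValidationError(
                            "not enough samples to designate references")
                c += 1
        eps = rng.standard_normal((F, n))
        for j in range(n):
            c = conds[j]
            cond_effect = beta[:, c - 1] if c >= 1 else 0.0
            values[:, col] = (alpha + cond_effect + gamma[i]
                              + delta[i] * eps[:, j])
            sample_ids.append(f"{b}_s{j + 1:02d}")
            batches.append(b)
            conditions.append(f"cond{c + 1}")
            is_ref.append(ref_flags[j])
            col += 1

    matrix = OmicsMatrix.from_arrays(
        values, [f"f{k + 1:04d}" for k in range(F)], sample_ids)
    table = pd.DataFrame({"batch": batches, "label": conditions},
                         index=pd.Index(sample_ids, name="sample"))
    meta = SampleMeta(table=table, batch_col="batch", label_col="label",
                      is_reference=pd.Series(is_ref, index=table.index))
    truth = GroundTruth(alpha=alpha, beta=beta, gamma=gamma, delta=delta,
                        conditions=table["label"].copy(), batch_ids=batch_ids)
    if cfg.missing_fraction > 0:
        matrix = apply_feature_mcar(matrix, meta, cfg.missing_fraction, rng=rng)
    return matrix, meta, truth


def apply_feature_mcar(matrix: OmicsMatrix, meta: SampleMeta,
                       missing_fraction: float,
                       seed: Optional[int] = None,
                       rng: Optional[np.random.Generator] = None) -> OmicsMatrix:
    """Set a random fraction of features fully missing, per batch.

    Whole (feature, batch) blocks are blanked — no partial missingness is
    introduced, so subsequent singleton removal deletes nothing.
    """
    if not (0.0 <= missing_fraction < 1.0):
        raise DataValidationError("missing_fraction must be in [0, 1)")
    if missing_fraction == 0.0:
        return matrix.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    meta = meta.validate_against(matrix)
    values = matrix.values.copy()
    F = values.shape[0]
    n_missing = int(round(missing_fraction * F))
    batches = meta.batches.to_numpy()
    for b in meta.batch_order():
        cols = batches == b
        feats = rng.choice(F, size=n_missing, replace=False)
        values[np.ix_(feats, cols)] = np.nan
    observed_batches = np.zeros(F, dtype=int)
    for b in meta.batch_order():
        cols = batches == b
        observed_batches += (~np.isnan(values[:, cols])).any(axis=1)
    if (observed_batches < 2).any():
        logger.warning(
            "%d feature(s) observed in fewer than 2 batches after MCAR "
            "masking; they cannot be corrected against any other batch",
            int((observed_batches < 2).sum()))
    return matrix.with_values(values)


def make_imbalanced_pair(
    n_features: int = 600,
    samples_per_class: int = 10,
    depletion: int = 0,
    n_references_per_batch: int = 0,
    missing_fraction: float = 0.1,
    seed: Optional[int] = None,
) -> tuple[OmicsMatrix, SampleMeta]:
    """Two-batch dataset with symmetric class imbalance.

    Starting from two balanced batches (``samples_per_class`` per
    condition), ``depletion`` non-reference samples of condition 1 are
    removed from batch 1 and of condition 2 from batch 2.  Optional
    references (spread across conditions) are never removed.
    """
    if depletion < 0:
        raise DataValidationError("depletion must be >= 0")
    cfg = SimConfig(
        n_features=n_features, n_batches=2,
        samples_per_batch=2 * samples_per_class, n_conditions=2,
        randomize_minority=False, missing_fraction=missing_fraction,
        n_references_per_batch=n_references_per_batch, seed=seed,
    )
    matrix, meta, _ = generate(cfg)
    drop: list[str] = []
    for batch, cond in (("B01", "cond1"), ("B02", "cond2")):
        pool = meta.table.index[
            (meta.batches == batch) & (meta.table["label"] == cond)
            & ~meta.is_reference]
        if depletion > len(pool):
            raise DataValidationError(
                f"cannot deplete {depletion} non-reference samples of "
                f"{cond} from {batch}: only {len(pool)} available")
        drop.extend(pool[:depletion])
    keep = [s for s in matrix.sample_ids if s not in set(drop)]
    return OmicsMatrix(matrix.data[keep]), meta.subset(keep)
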