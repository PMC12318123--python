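"""The batch-effect reduction tree: planning, scheduling and execution.

The integration task over N batches is decomposed into a binary tree of
N - 1 pairwise correction-and-merge steps: at each level adjacent batches
(in input order) are paired, corrected with the chosen back-end, and
merged into a single intermediate batch for the next level; an odd batch
is carried over unpaired.  Features lacking data on one side of a pair are
propagated unchanged and picked up at a later level.

Execution may be parallelized under the P/R/S contract: P worker
processes handle the first tree level, the worker count is divided by R
after every level, and once at most S intermediate batches remain the
remaining steps run sequentially.  P, R and S control parallelism only —
the numeric output is identical for every setting, because each pairwise
step is a pure function of its two input batches.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .adjusters import correct_pair_values
from .datamodel import DataValidationError, OmicsMatrix, QCReport, SampleMeta
from .metrics import asw
from .preprocess import remove_singletons

__all__ = ["TreePlan", "SchedulingParams", "AdjustmentConfig",
           "build_tree", "schedule_parallel", "run_bert"]


@dataclass(frozen=True)
class TreePlan:
    """Binary pairing schedule over batch ids.

    ``levels[k]`` lists the (left, right) pairs corrected at level k;
    ``carried[k]`` names the batch carried over unpaired at that level
    (None if the level is even).  Merged nodes are named ``"left+right"``.
    """

    leaves: tuple[str, ...]
    levels: tuple[tuple[tuple[str, str], ...], ...]
    carried: tuple[Optional[str], ...]

    @property
    def n_steps(self) -> int:
        return sum(len(lv) for lv in self.levels)

    @staticmethod
    def merged_id(a: str, b: str) -> str:
        return f"{a}+{b}"


@dataclass(frozen=True)
class SchedulingParams:
    """P/R/S parallelization contract: worker count, reduction factor and
    the intermediate-batch count at which execution turns sequential."""

    P: int = 1
    R: int = 2
    S: int = 2

    def __post_init__(self) -> None:
        if self.P < 1 or self.R < 2 or self.S < 2:
            raise DataValidationError(
                "scheduling requires P >= 1, R >= 2, S >= 2")


@dataclass
class AdjustmentConfig:
    """Method choice and mode for one integration run.

    Covariate mode and reference mode are mutually exclusive; with neither,
    the naive variant runs.  ``compute_asw=False`` skips the silhouette QC
    (useful when only the corrected matrix is needed).
    """

    method: str = "combat"  # "combat" | "limma"
    covariate_cols: tuple[str, ...] = ()
    use_references: bool = False
    scheduling: SchedulingParams = field(default_factory=SchedulingParams)
    compute_asw: bool = True
    batch_order: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.method not in ("combat", "limma"):
            raise DataValidationError(
                f"method must be 'combat' or 'limma', got {self.method!r}")
        self.covariate_cols = tuple(self.covariate_cols)
        if self.covariate_cols and self.use_references:
            raise DataValidationError(
                "covariate mode and reference mode are mutually exclusive")


def build_tree(batch_ids: Sequence[str]) -> TreePlan:
    """Deterministic binary tree pairing adjacent batches in given order."""
    ids = list(batch_ids)
    if len(ids) != len(set(ids)):
        raise DataValidationError("batch ids must be distinct")
    if len(ids) < 2:
        raise DataValidationError("nothing to integrate: need >= 2 batches")
    leaves = tuple(ids)
    levels: list[tuple[tuple[str, str], ...]] = []
    carried: list[Optional[str]] = []
    active = ids
    while len(active) > 1:
        pairs = [(active[i], active[i + 1])
                 for i in range(0, len(active) - 1, 2)]
        odd = active[-1] if len(active) % 2 == 1 else None
        levels.append(tuple(pairs))
        carried.append(odd)
        active = [TreePlan.merged_id(a, b) for a, b in pairs]
        if odd is not None:
            active.append(odd)
    return TreePlan(leaves=leaves, levels=tuple(levels), carried=tuple(carried))


def schedule_parallel(plan: TreePlan, params: SchedulingParams) -> tuple[int, ...]:
    """Worker count per tree level — a pure function of (plan, params).

    Starts at P workers, divides by R (floor, min 1) after each level, and
    forces sequential execution once the level starts with at most S
    active batches.
    """
    workers: list[int] = []
    current = params.P
    active = len(plan.leaves)
    for pairs in plan.levels:
        if active <= params.S:
            workers.append(1)
        else:
            workers.append(max(1, min(current, len(pairs))))
            current = max(1, current // params.R)
        active = len(pairs) + (1 if active % 2 == 1 else 0)
    return tuple(workers)


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _pair_task(values: np.ndarray, in_b: np.ndarray, method: str,
               cov: Optional[pd.DataFrame], ref_mask: Optional[np.ndarray]
               ) -> np.ndarray:
    return correct_pair_values(values, in_b, method, cov=cov, ref_mask=ref_mask)


def run_bert(matrix: OmicsMatrix, meta: SampleMeta,
             config: Optional[AdjustmentConfig] = None
             ) -> tuple[OmicsMatrix, QCReport]:
    """Integrate all batches of ``matrix`` and report QC metrics.

    Returns the corrected matrix with feature and sample order identical
    to the input, plus a :class:`QCReport`.  Numeric values are lost only
    during singleton removal; every pairwise step either corrects a
    feature or passes it through bit-identically.
    """
    if config is None:
        config = AdjustmentConfig()
    meta = meta.validate_against(matrix)
    n_in = matrix.n_numeric

    asw_batch_raw = asw_label_raw = None
    if config.compute_asw:
        asw_batch_raw = asw(matrix, meta.batches, "batch").asw
        if meta.labels is not None:
            asw_label_raw = asw(matrix, meta.labels, "label").asw

    pre, removed = remove_singletons(matrix, meta)

    order = list(config.batch_order) if config.batch_order is not None \
        else meta.batch_order()
    if set(order) != set(meta.batch_order()):
        raise DataValidationError("batch_order must permute the input batches")
    plan = build_tree(order)
    workers_per_level = schedule_parallel(plan, config.scheduling)

    cov_table = meta.table[list(config.covariate_cols)] \
        if config.covariate_cols else None
    ref_flags = meta.is_reference.to_numpy() if config.use_references else None
    if config.use_references and ref_flags is not None:
        batches_arr = meta.batches.to_numpy()
        for b in order:
            if not ref_flags[batches_arr == b].any():
                raise DataValidationError(
                    f"reference mode requires >= 1 reference sample per "
                    f"batch; batch {b!r} has none")

    work = pre.values.copy()
    batch_of = meta.batches.to_numpy().astype(object)
    t0 = time.perf_counter()
    for level_idx, pairs in enumerate(plan.levels):
        n_workers = workers_per_level[level_idx]
        tasks = []
        for a, b in pairs:
            cols = (batch_of == a) | (batch_of == b)
            in_b = batch_of[cols] == b
            sub_cov = cov_table.loc[cols] if cov_table is not None else None
            sub_ref = ref_flags[cols] if ref_flags is not None else None
            tasks.append((cols, work[:, cols], in_b, sub_cov, sub_ref))
        if n_workers > 1 and len(tasks) > 1:
            results = Parallel(n_jobs=n_workers)(
                delayed(_pair_task)(vals, in_b, config.method, cov, ref)
                for _, vals, in_b, cov, ref in tasks)
        else:
            results = [_pair_task(vals, in_b, config.method, cov, ref)
                       for _, vals, in_b, cov, ref in tasks]
        for (cols, *_), corrected in zip(tasks, results):
            work[:, cols] = corrected
        for a, b in pairs:
            merged = TreePlan.merged_id(a, b)
            batch_of[(batch_of == a) | (batch_of == b)] = merged
    elapsed = time.perf_counter() - t0

    corrected = pre.with_values(work)
    asw_batch_corr = asw_label_corr = None
    if config.compute_asw:
        asw_batch_corr = asw(corrected, meta.batches, "batch").asw
        if meta.labels is not None:
            asw_label_corr = asw(corrected, meta.labels, "label").asw

    report = QCReport(
        n_numeric_in=n_in,
        n_numeric_removed_preprocessing=removed,
        n_numeric_out=corrected.n_numeric,
        asw_batch_raw=asw_batch_raw,
        asw_batch_corrected=asw_batch_corr,
        asw_label_raw=asw_label_raw,
        asw_label_corrected=asw_label_corr,
        elapsed_seconds=elapsed,
        n_pairwise_steps=plan.n_steps,
    )
    return corrected, report
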