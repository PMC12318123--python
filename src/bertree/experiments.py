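"""Seed-controlled simulation experiments.

Each experiment draws datasets from the generative model in
:mod:`bertree.simulate`, runs the tree-based correction, and records
per-repetition ASW scores, value counts, step counts and elapsed time.
Defaults follow the desk-scale study designs (10 repetitions, 6000
features); ``fast=True`` shrinks them (3 repetitions, 2000 features) for
quick runs.  Elapsed time is recorded but never asserted anywhere —
runtimes are hardware-dependent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adjusters import correct_onestep_linear, correct_pair_values
from .datamodel import OmicsMatrix
from .metrics import asw
from .simulate import SimConfig, generate, make_imbalanced_pair
from .tree import AdjustmentConfig, run_bert

__all__ = ["ExperimentResult", "exp_missingness_sweep", "exp_batch_scaling",
           "exp_imbalance_covariates", "exp_order_invariance",
           "run_experiment"]


@dataclass
class ExperimentResult:
    name: str
    records: list[dict] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)

    def summary(self) -> dict:
        """Mean and sd per numeric record field, recomputed from records."""
        out: dict[str, dict[str, float]] = {}
        if not self.records:
            return out
        keys = [k for k, v in self.records[0].items()
                if isinstance(v, (int, float)) and not isinstance(v, bool)]
        for k in keys:
            vals = np.array([r[k] for r in self.records if r.get(k) is not None],
                            dtype=float)
            if len(vals):
                out[k] = {"mean": float(vals.mean()),
                          "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps({"name": self.name, "seeds": self.seeds,
                           "records": self.records, "summary": self.summary()},
                          indent=indent)


def _rep_seeds(seed: Optional[int], reps: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2 ** 31) for s in ss.generate_state(reps)]


def exp_missingness_sweep(
    reps: int = 10,
    fractions: Sequence[float] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
    methods: Sequence[str] = ("limma", "combat"),
    n_features: int = 6000,
    n_batches: int = 20,
    samples_per_batch: int = 10,
    seed: Optional[int] = None,
    fast: bool = False,
) -> ExperimentResult:
    """ASW and retained-value fraction across missing-value ratios.

    At fraction 0 the limma record also carries the ASW of the one-step
    whole-matrix linear correction for the equivalence comparison.
    """
    if fast:
        reps, n_features = 3, 2000
    seeds = _rep_seeds(seed, reps)
    res = ExperimentResult(name="missingness", seeds=seeds)
    for rep, s in enumerate(seeds):
        for frac in fractions:
            cfg = SimConfig(n_features=n_features, n_batches=n_batches,
                            samples_per_batch=samples_per_batch,
                            missing_fraction=frac, seed=s)
            matrix, meta, _ = generate(cfg)
            for method in methods:
                corrected, qc = run_bert(
                    matrix, meta, AdjustmentConfig(method=method))
                rec = {
                    "rep": rep, "fraction": frac, "method": method,
                    "n_numeric_in": qc.n_numeric_in,
                    "n_numeric_out": qc.n_numeric_out,
                    "removed_preprocessing": qc.n_numeric_removed_preprocessing,
                    "retained_fraction": qc.n_numeric_out / qc.n_numeric_in,
                    "asw_batch_raw": qc.asw_batch_raw,
                    "asw_label_raw": qc.asw_label_raw,
                    "asw_batch_corrected": qc.asw_batch_corrected,
                    "asw_label_corrected": qc.asw_label_corrected,
                    "elapsed_seconds": qc.elapsed_seconds,
                    "n_pairwise_steps": qc.n_pairwise_steps,
                }
                if frac == 0.0 and method == "limma":
                    onestep = correct_onestep_linear(matrix, meta)
                    rec["asw_batch_onestep"] = asw(onestep, meta.batches,
                                                   "batch").asw
                    rec["asw_label_onestep"] = asw(onestep, meta.labels,
                                                   "label").asw
                res.records.append(rec)
    return res


def exp_batch_scaling(
    reps: int = 3,
    batch_counts: Sequence[int] = (4, 8, 16, 32, 64),
    method: str = "limma",
    n_features: int = 6000,
    samples_per_batch: int = 10,
    missing_fraction: float = 0.2,
    seed: Optional[int] = None,
    fast: bool = False,
) -> ExperimentResult:
    """Pairwise-step counts (must be N - 1) and runtime across batch counts."""
    if fast:
        reps, n_features = 2, 1000
    seeds = _rep_seeds(seed, reps)
    res = ExperimentResult(name="scaling", seeds=seeds)
    for rep, s in enumerate(seeds):
        for nb in batch_counts:
            cfg = SimConfig(n_features=n_features, n_batches=nb,
                            samples_per_batch=samples_per_batch,
                            missing_fraction=missing_fraction, seed=s)
            matrix, meta, _ = generate(cfg)
            _, qc = run_bert(matrix, meta,
                             AdjustmentConfig(method=method, compute_asw=False))
            res.records.append({
                "rep": rep, "n_batches": nb,
                "n_pairwise_steps": qc.n_pairwise_steps,
                "n_numeric_in": qc.n_numeric_in,
                "n_numeric_out": qc.n_numeric_out,
                "removed_preprocessing": qc.n_numeric_removed_preprocessing,
                "elapsed_seconds": qc.elapsed_seconds,
                "seconds_per_batch": qc.elapsed_seconds / nb,
            })
    return res


def exp_imbalance_covariates(
    reps: int = 10,
    ratios: Sequence[tuple[int, int]] = ((1, 9), (3, 7), (5, 5)),
    n_batches: int = 8,
    samples_per_batch: int = 80,
    n_features: int = 6000,
    seed: Optional[int] = None,
    fast: bool = False,
) -> ExperimentResult:
    """Naive vs covariate-aware ComBat under per-batch class imbalance.

    The minority class is drawn at random per batch.  Under strong
    imbalance the naive batch-mean estimate absorbs class composition and
    correction erodes the biological signal; conditioning on the class as
    a covariate protects it.
    """
    if fast:
        reps, n_features = 3, 2000
    seeds = _rep_seeds(seed, reps)
    res = ExperimentResult(name="imbalance", seeds=seeds)
    for rep, s in enumerate(seeds):
        for a, b in ratios:
            ratio = (a / (a + b), b / (a + b))
            cfg = SimConfig(n_features=n_features, n_batches=n_batches,
                            samples_per_batch=samples_per_batch,
                            class_ratio=ratio, randomize_minority=True,
                            seed=s)
            matrix, meta, _ = generate(cfg)
            _, qc_naive = run_bert(matrix, meta,
                                   AdjustmentConfig(method="combat"))
            _, qc_cov = run_bert(
                matrix, meta,
                AdjustmentConfig(method="combat", covariate_cols=("label",)))
            res.records.append({
                "rep": rep, "ratio": f"{a}:{b}",
                "asw_label_raw": qc_naive.asw_label_raw,
                "asw_label_naive": qc_naive.asw_label_corrected,
                "asw_label_covariate": qc_cov.asw_label_corrected,
                "asw_batch_naive": qc_naive.asw_batch_corrected,
                "asw_batch_covariate": qc_cov.asw_batch_corrected,
                "elapsed_naive": qc_naive.elapsed_seconds,
                "elapsed_covariate": qc_cov.elapsed_seconds,
            })
    return res


def exp_order_invariance(
    reps: int = 3,
    methods: Sequence[str] = ("limma", "combat"),
    n_features: int = 2000,
    n_batches: int = 8,
    samples_per_batch: int = 10,
    missing_fraction: float = 0.2,
    seed: Optional[int] = None,
    fast: bool = False,
) -> ExperimentResult:
    """Effect of batch-processing order on the corrected values.

    For a random permutation of the batch order, records the maximum
    per-feature standard deviation of the difference between the two
    outputs (zero would mean the orders differ only by per-feature
    constants) and the absolute ASW difference with respect to the label.
    """
    if fast:
        reps, n_features = 2, 1000
    seeds = _rep_seeds(seed, reps)
    res = ExperimentResult(name="order", seeds=seeds)
    for rep, s in enumerate(seeds):
        cfg = SimConfig(n_features=n_features, n_batches=n_batches,
                        samples_per_batch=samples_per_batch,
                        missing_fraction=missing_fraction, seed=s)
        matrix, meta, _ = generate(cfg)
        rng = np.random.default_rng(s)
        order = meta.batch_order()
        perm = [order[i] for i in rng.permutation(len(order))]
        for method in methods:
            out1, _ = run_bert(matrix, meta,
                               AdjustmentConfig(method=method, compute_asw=False))
            out2, _ = run_bert(matrix, meta,
                               AdjustmentConfig(method=method, compute_asw=False,
                                                batch_order=perm))
            diff = out2.values - out1.values
            observed = (~np.isnan(diff)).sum(axis=1) > 0
            with np.errstate(invalid="ignore"):
                feat_std = np.nanstd(diff[observed], axis=1)
            asw1 = asw(out1, meta.labels, "label").asw
            asw2 = asw(out2, meta.labels, "label").asw
            res.records.append({
                "rep": rep, "method": method,
                "max_feature_std_of_diff": float(np.nanmax(feat_std)),
                "abs_asw_label_diff": abs(asw1 - asw2),
            })
    return res


_EXPERIMENTS = {
    "missingness": exp_missingness_sweep,
    "scaling": exp_batch_scaling,
    "imbalance": exp_imbalance_covariates,
    "order": exp_order_invariance,
}


def run_experiment(name: str, seed: Optional[int] = None,
                   fast: bool = False, **kwargs) -> ExperimentResult:
    if name not in _EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; "
                         f"choose from {sorted(_EXPERIMENTS)}")
    return _EXPERIMENTS[name](seed=seed, fast=fast, **kwargs)
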