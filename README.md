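# bertree — batch-effect reduction trees for incomplete omics matrices

Quantitative omics experiments (isobaric-labelling proteomics,
metabolomics, micro-arrays) are acquired in batches, and each batch
imprints a systematic technical bias on every feature it measures.
Classical correctors such as ComBat and limma's `removeBatchEffect`
require every batch to contain numeric values for every feature — a
condition that real proteomics matrices, where a peptide is often
quantified in some batches and absent from others, rarely meet.

`bertree` integrates an arbitrary number of batches without imputation by
decomposing the task into a **binary tree of pairwise correction steps**:
at each tree level adjacent batches are paired, corrected, and merged into
intermediate batches, so N batches are integrated in exactly N − 1
pairwise steps.  Within a pair, a feature is corrected whenever both
batches hold at least two numeric values for it; otherwise it is
propagated to the next level unchanged and corrected once a partner batch
with data appears.  Apart from an initial pass that deletes values that
are alone in their (feature, batch) cell, no numeric value is ever lost.

Per pair, features follow the location/scale model

```
y_ijf = alpha_f + X beta_f + gamma_if + delta_if * eps_ijf
```

with feature baseline `alpha_f`, covariate effects `beta_f` for the design
`X`, additive batch effect `gamma_if` and multiplicative batch effect
`delta_if`.  Two back-ends are provided:

* **combat** — parametric empirical Bayes: per-feature batch
  location/scale estimates are shrunk toward a normal / inverse-gamma
  prior fitted across features, then removed;
* **limma** — per-feature ordinary least squares on an intercept,
  a sum-to-zero batch indicator and dummy-coded covariates; only the
  batch term is subtracted.

Biological conditions known for every sample can be supplied as
categorical covariates; alternatively, user-flagged **reference samples**
anchor the batch-effect estimate, which is then applied to all samples.
Integration quality is reported as the average silhouette width (ASW,
in [−1, 1]) with respect to batch of origin (lower = better mixing) and
biological label (higher = better-preserved signal), using
pairwise-complete Euclidean distances rescaled by `sqrt(F_total/F_shared)`.

## Worked example

Simulate five batches of ten samples with 20 % of features missing per
batch, then integrate with the empirical-Bayes back-end:

```sh
$ printf 'n_features: 600\nn_batches: 5\nsamples_per_batch: 10\nmissing_fraction: 0.2\n' > sim.yaml
$ bert simulate --config sim.yaml --seed 11 --out-matrix M.tsv --out-meta meta.tsv
wrote 600 features x 50 samples (24000 numeric values)
$ bert run --matrix M.tsv --meta meta.tsv --method combat --label-col label --out outdir
4 pairwise steps, 24000/24000 numeric values retained, 0.01s correction time
ASW batch: 0.3871 -> -0.0716
ASW label: 0.1749 -> 0.4477
```

Five batches were integrated in 5 − 1 = 4 pairwise steps and every
numeric value survived.  Before correction, samples clustered by batch
(ASW batch 0.39) more than by condition (ASW label 0.17); afterwards the
batch structure is gone (−0.07, near the value expected for random
grouping) while the biological separation has sharpened (0.45).
The corrected matrix (`outdir/corrected.tsv`, original row and column
order) and the QC report (`outdir/qc_report.json`) are written to the
output directory.

The same pipeline is available as a library:

```python
from bertree import SimConfig, generate, run_bert, AdjustmentConfig

matrix, meta, truth = generate(SimConfig(n_batches=5, seed=11))
corrected, report = run_bert(matrix, meta, AdjustmentConfig(method="combat"))
```

`bert experiment --name {missingness,scaling,imbalance,order}` reruns the
scripted simulation studies (missing-value sweep, batch-count scaling,
covariate rescue under class imbalance, batch-order invariance);
`--fast` shrinks repetitions and feature counts.

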