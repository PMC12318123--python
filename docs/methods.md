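# Methods

## Model

All correction back-ends assume log-scale intensities following the
generalized location/scale model per feature `f`, sample `j`, batch `i`:

```
y_ijf = alpha_f + X beta_f + gamma_if + delta_if * eps_ijf,   eps ~ N(0, 1)
```

`alpha_f` is the feature baseline, `X beta_f` the contribution of known
categorical covariates (dummy-coded), `gamma_if` an additive and
`delta_if > 0` a multiplicative batch effect.  Correction means removing
`gamma` and `delta` while retaining `alpha` and `X beta`.

## Pairwise correction

### Eligibility and propagation

Every estimator needs at least two numeric values per feature within each
batch it touches.  Pre-processing therefore deletes values that are alone
in their (feature, batch) cell ("singleton removal"), after which every
cell holds 0 or ≥ 2 values.  Singleton removal runs once, on the original
input batches: merging batches can only increase per-feature counts, so
intermediate batches never need re-screening (verified by idempotence
tests).  Within a pair, a feature with data on both sides is corrected;
with data on one side it is propagated bit-identically and corrected at a
later tree level; with no data it is trivially absent.  In reference mode
a feature additionally needs ≥ 2 numeric *reference* values per batch —
the same threshold as the general rule, since the shift is estimated from
references only.

### Empirical-Bayes location/scale back-end (`combat`)

Per pair: (1) fit per-feature batch means (one-hot) plus covariate
dummies by least squares over observed entries; (2) standardize with the
observed-count-weighted grand mean and the pooled residual variance
(denominator: total observed count per feature); (3) estimate per-batch
location (`gamma_hat`, mean of standardized data) and scale
(`delta2_hat`, unbiased variance); (4) fit priors across features by
method of moments — normal for location, inverse-gamma (moment-matched
shape/scale) for squared scale; (5) solve the coupled posterior-mean
equations iteratively until the largest absolute parameter change falls
below 1e-6 (at most 100 iterations; both values fixed for
reproducibility to float tolerance); (6) subtract the shrunken location,
divide by the shrunken scale, and back-transform.  Missingness is handled
by replacing every `n` with the per-feature per-batch observed count.
Tests cross-check the implementation against `sva::ComBat` on complete
data (agreement ~1e-5; the remaining gap is sva's looser iteration
stopping rule) and against an independent scalar-loop implementation
(1e-10).

Degenerate cases: features with zero pooled variance are propagated
unchanged with a warning (scale correction undefined); if the prior
moments degenerate (fewer than two correctable features, or zero
across-feature variance of the estimates), shrinkage is skipped and the
raw per-batch estimates are used.

### Linear back-end (`limma`)

Per feature, OLS of observed values on intercept + batch + covariate
dummies; only the fitted batch term is subtracted.  The batch indicator
is **sum-to-zero coded** (+1 / −1), so the shift is split symmetrically
across the two batches rather than designating a reference batch: any
global offset is irrelevant downstream, and symmetry makes batch-swap
invariance exact.  Features sharing a missingness pattern are solved as
one multi-RHS least-squares system.  Agreement with
`limma::removeBatchEffect` (which uses the same contrast) is to 1e-10 on
complete data.

Rank-deficient designs — e.g. a covariate level perfectly confounded
with batch — raise an error naming the collinear columns; covariates are
never silently dropped.  Covariate levels present in only one batch are
allowed as long as the design keeps full rank.

### Reference mode

The batch shift is estimated by the linear back-end restricted to
flagged reference samples (plain OLS, references unweighted by batch
size), then subtracted from *all* samples of each batch.  Intended for
designs where conditions are known only for a few anchor samples;
reference and covariate modes are mutually exclusive.

## The tree

Batches are paired adjacently in input order, deterministically; an odd
batch is carried to the next level.  N batches always take exactly N − 1
pairwise steps.  Merged pairs are treated as single batches at the next
level.  The pairing order is immaterial up to per-feature constants for
the linear back-end: each step equalizes the pair's feature means and
leaves within-batch deviations untouched, so any order ends with all
batch means equal and outputs differing only by a per-feature offset
(measured: per-feature std of the difference ~1e-15, label-ASW difference
~1e-16).  The empirical-Bayes back-end is *not* order-invariant in this
strict sense — its variance pooling depends on the tree shape, so
rescaling differs slightly between orders (per-feature std of the
difference ~0.1 on typical simulations, label-ASW difference ~1e-5); the
order experiment records this without asserting it.

For the same reason the tree with the linear back-end is equivalent to a
single whole-matrix linear correction up to per-feature constants, which
Euclidean distances cancel — hence identical ASW scores up to
floating-point noise.

### Parallel execution (P/R/S)

The first tree level may run on P worker processes (joblib, process
pool); the worker count is divided by R (floor, minimum 1) after each
level, and once a level starts with at most S active batches the rest
runs sequentially.  Each pairwise step is a pure function of its two
input batches, so P, R and S change scheduling only — outputs are
bitwise identical for the linear back-end and within accumulation noise
(≤ 1e-12) for the empirical-Bayes back-end.  Tasks are one pairwise step
each; distributed-memory execution is out of scope, represented only by
this scheduling contract.  Elapsed time is measured wall-clock around
the correction phases (I/O and QC excluded).

## Quality metrics

ASW is the mean over samples of `(b_i − a_i)/max(a_i, b_i)` with `a_i`
the mean distance to the own group and `b_i` the smallest mean distance
to another group; members of singleton groups score 0.  The printed
range [−1, 1] requires the mean (not the bare sum) over samples, which is
what is implemented.  Distances are Euclidean over the features observed
in both samples, rescaled by `sqrt(F_total/F_shared)`; a pair sharing no
features is an error.  The distance convention is isolated behind
`pairwise_distances` so it can be swapped.

## Simulator

`simulate.generate` draws `alpha`, `beta`, `gamma` from the standard
normal and `delta` from an inverse-gamma with shape 5 and scale 2
(density ∝ x^(−shape−1) exp(−scale/x), mean = scale/(shape−1) = 0.5).
Defaults mirror the simulation study design: 6000 features, 20 batches
of 10 samples, two conditions.  Missingness is feature-wise MCAR per
batch: a fraction of features is blanked completely within a batch,
never partially — emulating batch-level peptide dropout in isobaric
labelling.  Class imbalance assigns per-batch condition counts from a
ratio, with the minority class placed at random per batch;
`make_imbalanced_pair` builds the two-batch design in which condition 1
is depleted from batch 1 and condition 2 from batch 2, keeping optional
reference samples (spread one per condition) untouched.

What the simulator does *not* emulate: intensity-dependent (MNAR /
detection-limit) missingness, correlated features, heavy-tailed noise,
unequal batch sizes, continuous covariates.  Passing tests on this
generator therefore demonstrate correctness of the estimators under the
stated model, not robustness to every property of real data.

## Experiment and test problem sizes

The scripted experiments default to the study design above with 10
repetitions; `fast=True` uses 3 repetitions and 2000 features.  The test
suite runs reduced sizes throughout (hundreds to a few thousand
features, repetition counts 3–10) — chosen so each directional claim is
still decided far from its threshold, e.g. the covariate-rescue gap at
1:9 imbalance is ~0.3 ASW against a 0 threshold, and the
tree-vs-one-step ASW differences sit at 1e-15 against bounds of 0.01 /
0.09.  The acceptance script runs the full 6000-feature, 10-repetition
design.  The imbalance trend test is a one-sided Spearman correlation
(degradation direction): with shrinking sample counts the label ASW
drifts slightly *upward* for purely compositional reasons, which a
two-sided test would flag despite zero degradation.

## Known limitations

* Only categorical covariates; continuous covariates are rejected by
  design (dummy coding).
* The empirical-Bayes back-end is the parametric variant; non-parametric
  priors and mean-only mode are not implemented.
* Batch-order invariance holds exactly (up to offsets) for the linear
  back-end only; see above for the empirical-Bayes caveat.
* Count-based sequencing data (negative-binomial models) are out of
  scope; inputs are assumed log-scale continuous.
* I/O is in-memory delimited text; no HDF5/streaming backends.
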