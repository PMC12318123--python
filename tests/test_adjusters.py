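import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from bertree import (DataValidationError, DesignError, SimConfig,
                     correct_onestep_linear, correct_pair_combat,
                     correct_pair_linear, correct_pair_references, generate)

from conftest import make_pair

NA = np.nan


class TestLinear:
    def test_closed_form_two_constant_batches(self):
        """Batch A {0,0}, batch B {4,4}: sum-to-zero coding centres both
        batches on the common mean 2."""
        m, meta = make_pair([[0.0, 0.0, 4.0, 4.0]], ["A", "A", "B", "B"])
        out = correct_pair_linear(m, meta)
        assert np.allclose(out.values, 2.0)

    def test_identical_batches_unchanged(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((20, 3))
        m, meta = make_pair(np.hstack([block, block]), ["A"] * 3 + ["B"] * 3)
        out = correct_pair_linear(m, meta)
        assert np.array_equal(out.values, m.values)

    def test_batch_swap_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((30, 8))
        m1, meta1 = make_pair(vals, ["A"] * 4 + ["B"] * 4)
        m2, meta2 = make_pair(vals, ["B"] * 4 + ["A"] * 4)
        out1 = correct_pair_linear(m1, meta1)
        out2 = correct_pair_linear(m2, meta2)
        assert np.array_equal(out1.values, out2.values)

    def test_confounded_covariate_raises_naming_column(self):
        rng = np.random.default_rng(2)
        m, meta = make_pair(rng.standard_normal((5, 6)),
                            ["A"] * 3 + ["B"] * 3,
                            covariates={"grp": ["x", "x", "x", "y", "y", "y"]})
        with pytest.raises(DesignError, match="grp=y"):
            correct_pair_linear(m, meta, covariate_cols=("grp",))

    def test_covariate_effect_retained(self):
        """With a covariate in the design, the covariate contribution must
        survive correction while the batch shift is removed."""
        cov = ["x", "y", "x", "y", "x", "y", "x", "y"]
        batch = ["A"] * 4 + ["B"] * 4
        base = np.array([0.0, 3.0, 0.0, 3.0, 0.0, 3.0, 0.0, 3.0])
        shifted = base + np.where(np.array(batch) == "B", 5.0, 0.0)
        m, meta = make_pair(shifted[None, :], batch, covariates={"c": cov})
        out = correct_pair_linear(m, meta, covariate_cols=("c",))
        assert np.allclose(out.values[0], base + 2.5)  # common batch mean

    def test_propagates_feature_fully_missing_in_one_batch(self):
        vals = [[1.0, 2.0, NA, NA],
                [1.0, 2.0, 7.0, 9.0]]
        m, meta = make_pair(vals, ["A", "A", "B", "B"])
        out = correct_pair_linear(m, meta)
        assert np.array_equal(np.nan_to_num(out.values[0]),
                              np.nan_to_num(np.array(vals[0])))
        assert not np.allclose(out.values[1], vals[1])

    def test_mask_never_changes(self):
        rng = np.random.default_rng(3)
        vals = rng.standard_normal((40, 10))
        vals[rng.random(vals.shape) < 0.3] = NA
        m, meta = make_pair(vals, ["A"] * 5 + ["B"] * 5)
        from bertree import remove_singletons
        m, _ = remove_singletons(m, meta)
        out = correct_pair_linear(m, meta)
        assert np.array_equal(out.mask, m.mask)

    def test_requires_exactly_two_batches(self):
        m, meta = make_pair(np.zeros((2, 6)), ["A", "A", "B", "B", "C", "C"])
        with pytest.raises(DataValidationError, match="exactly 2"):
            correct_pair_linear(m, meta)


class TestReferences:
    def test_closed_form_shift_from_references(self):
        """Refs A {0,0} / B {3,3}: estimated shift 3 split symmetrically;
        non-references move by the same per-batch constant."""
        vals = [[0.0, 0.0, 10.0, 10.0, 3.0, 3.0, 13.0, 13.0]]
        batch = ["A"] * 4 + ["B"] * 4
        refs = [True, True, False, False, True, True, False, False]
        m, meta = make_pair(vals, batch, refs=refs)
        out = correct_pair_references(m, meta)
        expect = [1.5, 1.5, 11.5, 11.5, 1.5, 1.5, 11.5, 11.5]
        assert np.allclose(out.values[0], expect)

    def test_identical_references_zero_shift(self):
        vals = [[1.0, 2.0, 9.0, 1.0, 2.0, -4.0]]
        batch = ["A"] * 3 + ["B"] * 3
        refs = [True, True, False, True, True, False]
        m, meta = make_pair(vals, batch, refs=refs)
        out = correct_pair_references(m, meta)
        assert np.array_equal(out.values, m.values)

    def test_batch_without_reference_is_error(self):
        m, meta = make_pair(np.zeros((3, 4)), ["A", "A", "B", "B"],
                            refs=[True, True, False, False])
        with pytest.raises(DataValidationError, match="reference"):
            correct_pair_references(m, meta)

    def test_feature_needs_two_reference_values_per_batch(self):
        """A feature missing on one reference keeps < 2 numeric reference
        values in that batch and must be propagated unchanged."""
        vals = [[0.0, NA, 10.0, 10.0, 3.0, 3.0, 13.0, 13.0],
                [0.0, 0.0, 10.0, 10.0, 3.0, 3.0, 13.0, 13.0]]
        batch = ["A"] * 4 + ["B"] * 4
        refs = [True, True, False, False, True, True, False, False]
        m, meta = make_pair(vals, batch, refs=refs)
        from bertree import remove_singletons
        m, _ = remove_singletons(m, meta)
        out = correct_pair_references(m, meta)
        assert np.array_equal(np.nan_to_num(out.values[0]),
                              np.nan_to_num(m.values[0]))
        assert not np.allclose(out.values[1], m.values[1])


class TestCombat:
    def test_null_effects_shrink_toward_no_change(self):
        """Two batches from the same distribution: empirical-Bayes shrinkage
        drives the correction toward the identity as n grows."""
        m, meta, _ = generate(SimConfig(n_features=500, n_batches=2,
                                        samples_per_batch=200,
                                        null_batch_effects=True, seed=9))
        out = correct_pair_combat(m, meta)
        assert np.abs(out.values - m.values).mean() < 0.05

    def test_removes_known_location_scale_effects(self):
        """On data drawn with known gamma/delta, the corrected pair has
        between-batch mean differences near 0 and variance ratios near 1."""
        m, meta, _ = generate(SimConfig(n_features=800, n_batches=2,
                                        samples_per_batch=200, seed=11))
        out = correct_pair_combat(m, meta)
        b = (meta.batches == "B02").to_numpy()
        mean_diff = out.values[:, b].mean(1) - out.values[:, ~b].mean(1)
        var_ratio = (out.values[:, b].var(1, ddof=1)
                     / out.values[:, ~b].var(1, ddof=1))
        assert abs(mean_diff.mean()) < 0.01
        assert abs(np.log(var_ratio).mean()) < 0.05
        # raw data had real effects of sd ~1
        raw_diff = m.values[:, b].mean(1) - m.values[:, ~b].mean(1)
        assert raw_diff.std() > 10 * mean_diff.std()

    def test_propagates_and_preserves_mask(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal((50, 12))
        vals[:10, 6:] = NA  # fully missing in batch B -> propagate
        m, meta = make_pair(vals, ["A"] * 6 + ["B"] * 6)
        out = correct_pair_combat(m, meta)
        assert np.array_equal(out.values[:10], vals[:10], equal_nan=True)
        assert np.array_equal(out.mask, m.mask)

    def test_zero_variance_feature_propagated(self):
        vals = np.vstack([np.full((1, 8), 3.0),
                          np.random.default_rng(6).standard_normal((20, 8))])
        m, meta = make_pair(vals, ["A"] * 4 + ["B"] * 4)
        out = correct_pair_combat(m, meta)
        assert np.array_equal(out.values[0], vals[0])

    def test_confounded_covariate_raises(self):
        rng = np.random.default_rng(7)
        m, meta = make_pair(rng.standard_normal((10, 6)),
                            ["A"] * 3 + ["B"] * 3,
                            covariates={"grp": ["x"] * 3 + ["y"] * 3})
        with pytest.raises(DesignError):
            correct_pair_combat(m, meta, covariate_cols=("grp",))


class TestOneStep:
    def test_centres_all_batch_means(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((30, 12))
        vals += np.repeat([0.0, 5.0, -2.0], 4)[None, :]
        m, meta = make_pair(vals, ["A"] * 4 + ["B"] * 4 + ["C"] * 4)
        out = correct_onestep_linear(m, meta)
        for b in ("A", "B", "C"):
            cols = (meta.batches == b).to_numpy()
            means_b = out.values[:, cols].mean(1)
            grand = np.stack([out.values[:, (meta.batches == x).to_numpy()].mean(1)
                              for x in ("A", "B", "C")]).mean(0)
            assert np.allclose(means_b, grand)


# ---------------------------------------------------------------------------
# independent R oracles (limma / sva from the Bioconductor stack)
# ---------------------------------------------------------------------------

needs_r = pytest.mark.skipif(shutil.which("Rscript") is None,
                             reason="Rscript not available")


def _r_correct(tmp_path, Y, batch, cov):
    pd.DataFrame(Y).to_csv(tmp_path / "mat.csv", index=False)
    pd.DataFrame({"batch": batch, "cov": cov}).to_csv(
        tmp_path / "meta.csv", index=False)
    rcode = f"""
    suppressMessages({{library(limma); library(sva)}})
    setwd("{tmp_path}")
    Y <- as.matrix(read.csv("mat.csv"))
    md <- read.csv("meta.csv")
    mod <- model.matrix(~cov, data=md)
    write.csv(removeBatchEffect(Y, batch=factor(md$batch), design=mod),
              "limma_out.csv", row.names=FALSE)
    write.csv(ComBat(Y, batch=factor(md$batch), mod=mod, par.prior=TRUE),
              "combat_out.csv", row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rcode], check=True, capture_output=True)
    return (pd.read_csv(tmp_path / "limma_out.csv").to_numpy(),
            pd.read_csv(tmp_path / "combat_out.csv").to_numpy())


@needs_r
def test_adjusters_agree_with_bioconductor_reference(tmp_path):
    """Cross-check both adjusters against limma::removeBatchEffect and
    sva::ComBat on complete two-batch data with a covariate."""
    rng = np.random.default_rng(7)
    F, nA, nB = 40, 8, 6
    shift = rng.standard_normal((F, 1))
    Y = rng.standard_normal((F, nA + nB))
    Y[:, nA:] += shift
    batch = ["A"] * nA + ["B"] * nB
    cov = list(rng.choice(["x", "y"], nA + nB))
    m, meta = make_pair(Y, batch, covariates={"cov": cov})
    r_limma, r_combat = _r_correct(tmp_path, Y, batch, cov)
    mine_limma = correct_pair_linear(m, meta, covariate_cols=("cov",)).values
    assert np.abs(mine_limma - r_limma).max() < 1e-10
    mine_combat = correct_pair_combat(m, meta, covariate_cols=("cov",)).values
    # sva stops its EB iteration at a looser relative tolerance
    assert np.abs(mine_combat - r_combat).max() < 1e-4
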