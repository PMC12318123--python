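import numpy as np
import pandas as pd
import pytest

from bertree import OmicsMatrix, SampleMeta


def make_pair(values, batches, labels=None, covariates=None, refs=None):
    """Build (OmicsMatrix, SampleMeta) from plain lists/arrays."""
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    sids = [f"s{i + 1}" for i in range(n)]
    fids = [f"f{i + 1}" for i in range(values.shape[0])]
    table = pd.DataFrame({"batch": list(batches)}, index=pd.Index(sids))
    label_col = None
    if labels is not None:
        table["label"] = list(labels)
        label_col = "label"
    cov_cols = ()
    if covariates is not None:
        for name, vals in covariates.items():
            table[name] = list(vals)
        cov_cols = tuple(covariates)
    is_ref = pd.Series(list(refs), index=table.index) if refs is not None else None
    matrix = OmicsMatrix.from_arrays(values, fids, sids)
    meta = SampleMeta(table=table, batch_col="batch", label_col=label_col,
                      covariate_cols=cov_cols, is_reference=is_ref)
    return matrix, meta


@pytest.fixture
def small_sim():
    """A small complete 4-batch simulated dataset with labels."""
    from bertree import SimConfig, generate
    return generate(SimConfig(n_features=200, n_batches=4,
                              samples_per_batch=8, seed=42))
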