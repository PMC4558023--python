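import numpy as np
import pandas as pd
import pytest

from polyload import ExpressionMatrix, SimParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated dataset shared by read-only tests."""
    params = SimParams(n_genes=60, n_mirnas=40, seed=101)
    return simulate_dataset(params)


@pytest.fixture()
def toy_expression():
    """Two genes / three isoforms x 2 samples x 2 fractions, hand-sized."""
    features = pd.DataFrame(
        {
            "gene_id": ["gA", "gA", "gB"],
            "rna_class": ["protein_coding", "protein_coding", "lincRNA"],
            "length_bases": [1000, 2000, 1500],
        },
        index=pd.Index(["gA.t0", "gA.t1", "gB.t0"], name="feature_id"),
    )
    cols = pd.MultiIndex.from_product(
        [["S1", "S2"], ["CYTOSOL", "POLYSOME"]], names=["sample_id", "fraction"]
    )
    counts = pd.DataFrame(
        [[30, 15, 40, 20], [70, 35, 60, 30], [100, 10, 120, 12]],
        index=features.index,
        columns=cols,
    )
    return ExpressionMatrix(features, counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
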