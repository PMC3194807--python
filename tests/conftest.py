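import warnings

import numpy as np
import pandas as pd
import pytest

from attract import ExpressionDataset


def make_dataset(values: np.ndarray, replicates: tuple[int, ...],
                 prefix: str = "G") -> ExpressionDataset:
    """Dataset from a raw array; columns grouped by class in order."""
    n_genes, n_samples = values.shape
    assert sum(replicates) == n_samples
    samples, labels = [], []
    for k, r in enumerate(replicates):
        for j in range(r):
            samples.append(f"C{k + 1}_s{j + 1}")
            labels.append(f"C{k + 1}")
    df = pd.DataFrame(values, index=[f"{prefix}{i}" for i in range(n_genes)],
                      columns=samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ExpressionDataset(df, pd.Series(labels, index=samples))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_group_gene():
    """The 4-sample, two-class, one-gene worked example (F = 8)."""
    return make_dataset(np.array([[1.0, 2.0, 3.0, 4.0]]), (2, 2))
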