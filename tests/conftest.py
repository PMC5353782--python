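import numpy as np
import pandas as pd
import pytest

from eigennet.dataset import ExpressionDataset


@pytest.fixture
def labelled_ds() -> ExpressionDataset:
    """Small handcrafted dataset: 4 genes x 6 samples, two conditions."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.normal(size=(4, 6)),
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )
    cond = pd.Series(["X", "X", "X", "Y", "Y", "Y"], index=values.columns)
    return ExpressionDataset(values, cond)


def make_dataset(matrix, genes=None, samples=None, condition=None) -> ExpressionDataset:
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    samples = samples or [f"s{j}" for j in range(matrix.shape[1])]
    values = pd.DataFrame(matrix, index=genes, columns=samples)
    cond = pd.Series(condition, index=samples) if condition is not None else None
    return ExpressionDataset(values, cond)
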