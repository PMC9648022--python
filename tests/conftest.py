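import numpy as np
import pandas as pd
import pytest

from cervtrans.io import ExpressionDataset


def make_dataset(values, stage, dataset_id="TEST", genes=None, samples=None):
    """Small ExpressionDataset from a plain array + stage codes."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=pd.DataFrame(values, index=genes, columns=samples),
        stage=pd.Series(list(stage), index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def staged_dataset(rng):
    """50 genes x 20 samples, 5 per stage, pure noise around gene baselines."""
    base = rng.normal(7, 2, 50)
    values = base[:, None] + rng.normal(0, 0.5, (50, 20))
    return make_dataset(values, np.repeat([0, 1, 2, 3], 5))
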