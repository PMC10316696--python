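import numpy as np
import pandas as pd
import pytest

from knockdag.dataset import Dataset, VariableMeta


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_dataset(rng):
    """20 x 5 continuous dataset with mild correlation."""
    cov = 0.3 ** np.abs(np.subtract.outer(np.arange(5), np.arange(5)))
    x = rng.standard_normal((20, 5)) @ np.linalg.cholesky(cov).T
    return Dataset.from_dataframe(pd.DataFrame(x, columns=list("abcde")))


@pytest.fixture
def mixed_dataset(rng):
    """Continuous pair plus an ordinal column with 3 levels."""
    x = rng.standard_normal((60, 2))
    codes = rng.integers(0, 3, 60).astype(float)
    meta = [
        VariableMeta("u", "continuous"),
        VariableMeta("v", "continuous"),
        VariableMeta("g", "ordinal", (0, 1, 2)),
    ]
    return Dataset(np.column_stack([x, codes]), meta)
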