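import numpy as np
import pytest

from hccdx.io import TabularDataset
from hccdx.schema import DatasetSchema, FeatureSpec


@pytest.fixture
def tiny_missing():
    """3x4 table with exactly 3 masked cells."""
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [5.0, np.nan, 7.0, np.nan],
                       [np.nan, 10.0, 11.0, 12.0]])
    mask = np.isnan(values)
    labels = np.array([0, 1, 1])
    return TabularDataset(values, mask, labels, ["a", "b", "c", "d"])


@pytest.fixture
def wide_schema():
    """Five ratio features with ranges wide enough that truncation is nil."""
    feats = [FeatureSpec(name=f"v{j}", kind="ratio", low=-60.0, high=80.0,
                         mean=10.0, sd=4.0) for j in range(5)]
    return DatasetSchema(features=feats)


@pytest.fixture
def separable():
    """Linearly separable one-informative-feature dataset."""
    rng = np.random.default_rng(5)
    n = 60
    y = np.repeat([0, 1], n // 2)
    x0 = np.where(y == 1, 2.0, -2.0) + rng.normal(0, 0.1, n)
    x1 = rng.normal(size=n)
    return np.column_stack([x0, x1]), y
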