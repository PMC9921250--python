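import numpy as np
import pandas as pd
import pytest

from probstack.schema import ColumnSpec, DatasetSchema, SemanticType, TabularDataset


def small_schema(feature_names, label="target", kind=SemanticType.NUMERIC_CONTINUOUS):
    cols = [ColumnSpec(n, kind) for n in feature_names]
    cols.append(ColumnSpec(label, SemanticType.BINARY))
    return DatasetSchema(columns=tuple(cols), label_column=label)


def make_dataset(X, y, feature_names=None, kind=SemanticType.NUMERIC_CONTINUOUS):
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    schema = small_schema(feature_names, kind=kind)
    values = pd.DataFrame(X, columns=feature_names)
    return TabularDataset(schema=schema, values=values, labels=np.asarray(y))


@pytest.fixture
def separable_dataset():
    """200 balanced rows, cleanly separated on two features."""
    rng = np.random.default_rng(42)
    n = 100
    X0 = rng.normal(loc=[-2.0, -2.0], scale=0.5, size=(n, 2))
    X1 = rng.normal(loc=[2.0, 2.0], scale=0.5, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    perm = rng.permutation(2 * n)
    return make_dataset(X[perm], y[perm])


@pytest.fixture
def noisy_dataset():
    """300 rows with a single moderately informative feature."""
    rng = np.random.default_rng(7)
    n = 300
    x0 = rng.normal(size=n)
    noise = rng.normal(size=(n, 3))
    p = 1.0 / (1.0 + np.exp(-1.2 * x0))
    y = (rng.random(n) < p).astype(int)
    return make_dataset(np.column_stack([x0, noise]), y)
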