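import numpy as np
import pandas as pd
import pytest

from qnbench import Dataset


def make_dataset(values, classes, batches, features=None, samples=None) -> Dataset:
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    features = features or [f"F{i+1}" for i in range(n_f)]
    samples = samples or [f"S{j+1}" for j in range(n_s)]
    frame = pd.DataFrame(values, index=features, columns=samples)
    return Dataset(
        frame,
        pd.Series(list(classes), index=samples),
        pd.Series(list(batches), index=samples),
    )


@pytest.fixture
def tiny_dataset() -> Dataset:
    """3 features x 2 samples, one class, one batch."""
    return make_dataset(
        [[5.0, 4.0], [2.0, 1.0], [3.0, 2.0]], ["A", "A"], ["Batch1", "Batch1"]
    )


@pytest.fixture
def two_class_dataset() -> Dataset:
    """20 features x 8 samples, 2 classes x 2 batches, reproducible."""
    rng = np.random.default_rng(42)
    values = np.exp(rng.normal(5.0, 1.0, size=(20, 8)))
    return make_dataset(
        values,
        ["A", "A", "A", "A", "B", "B", "B", "B"],
        ["Batch1", "Batch2"] * 4,
    )
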