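import numpy as np
import pytest

from editrf import FeatureTable, LabeledDataset, SyntheticSpec, generate


@pytest.fixture
def separable_dataset() -> LabeledDataset:
    """Two well-separated Gaussian blobs in two features; trivially learnable."""
    rng = np.random.default_rng(42)
    n = 40
    x0 = rng.normal(0.0, 0.3, size=(n, 2))
    x1 = rng.normal(5.0, 0.3, size=(n, 2))
    X = np.vstack([x0, x1])
    y = np.repeat([0, 1], n)
    return LabeledDataset(FeatureTable(X, ["a", "b"]), y)


@pytest.fixture
def small_synth() -> LabeledDataset:
    """60 samples, 3 informative + 2 redundant + 10 noise features."""
    return generate(
        SyntheticSpec(
            n_per_class=30, n_informative=3, n_redundant=2, n_noise=10,
            delta=2.0, redundant_noise_sd=0.1, seed=7,
        )
    )
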