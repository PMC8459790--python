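import numpy as np
import pytest

from mfsacec import synthetic


@pytest.fixture(scope="session")
def default_fixture():
    """The frozen 60 x 1000 reference dataset with ground truth."""
    return synthetic.default_fixture()


@pytest.fixture(scope="session")
def small_ds():
    """A small, strongly separable dataset for fast pipeline tests."""
    ds, truth = synthetic.generate(
        synthetic.SyntheticSpec(
            n_per_class=(14, 10), n_genes=60, n_informative=6,
            effect_size=4.0, block_correlation=0.6, seed=11,
        )
    )
    return ds, truth


@pytest.fixture
def two_class_labels():
    return np.array(["a"] * 10 + ["b"] * 10)


def random_instance(rng, max_u=12, max_v=8, n_classes=2):
    """A tiny random scoring problem for oracle sweeps."""
    u = int(rng.integers(n_classes * 2, max_u + 1))
    v = int(rng.integers(2, max_v + 1))
    X = rng.normal(size=(u, v))
    while True:
        y = rng.integers(0, n_classes, size=u)
        if len(np.unique(y)) == n_classes and np.bincount(y).min() >= 2:
            break
    classes = np.array([f"c{c}" for c in y])
    return X, classes
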