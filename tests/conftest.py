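import numpy as np
import pytest

from flowps import ClassifierConfig, ExpressionDataset


def make_ds(values, labels, prefix="s"):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    return ExpressionDataset(
        values,
        tuple(f"{prefix}{i}" for i in range(n)),
        tuple(f"g{j}" for j in range(s)),
        np.asarray(labels, dtype=int),
    )


def random_ds(seed, n=12, s=4, scale=1.0):
    """A balanced random dataset with continuous values (no ties)."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 100
    rng.shuffle(y)
    if not (y == 0).any() or not (y == 100).any():  # pragma: no cover
        y[0], y[1] = 0, 100
    return make_ds(rng.normal(scale=scale, size=(n, s)), y)


@pytest.fixture
def tiny_ds():
    """3 samples x 2 genes with labels {0, 100, 0}."""
    return make_ds([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], [0, 100, 0])


@pytest.fixture
def separable_ds():
    """Linearly separable 2-D data: class 0 at x<0, class 100 at x>0."""
    rng = np.random.default_rng(7)
    n = 16
    x0 = rng.normal(loc=-3, size=(n // 2, 2))
    x1 = rng.normal(loc=3, size=(n // 2, 2))
    vals = np.vstack([x0, x1])
    labels = [0] * (n // 2) + [100] * (n // 2)
    return make_ds(vals, labels)


@pytest.fixture
def default_config():
    return ClassifierConfig(kernel="linear", C=1.0, p=0.90)
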