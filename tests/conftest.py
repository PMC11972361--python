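import numpy as np
import pytest

from leopard import DataBlock, LongitudinalDataset, SyntheticSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_block():
    """3 samples x 2 variables with one missing cell."""
    values = np.array([[1.0, 4.0], [np.nan, 5.0], [3.0, 6.0]])
    mask = ~np.isnan(values)
    return DataBlock("v1", "t1", ["a", "b", "c"], ["x1", "x2"], values, mask)


@pytest.fixture
def small_spec():
    """A fast-to-fit cohort for training smoke tests."""
    return SyntheticSpec(n_subjects=80, n_variables=(12, 8), content_dim=4,
                         private_dim=2, seed=7)


@pytest.fixture
def small_dataset(small_spec):
    dataset, truth = simulate_dataset(small_spec)
    return dataset, truth


def make_dataset(n=6, p1=3, p2=2, views=("v1", "v2"), tps=("t1", "t2"), seed=0):
    """Dense fully-observed toy dataset with arbitrary geometry."""
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i}" for i in range(n)]
    blocks = {}
    for v, p in zip(views, (p1, p2)):
        for t in tps:
            vals = rng.normal(10, 1, size=(n, p))
            blocks[(v, t)] = DataBlock(v, t, list(sample_ids),
                                       [f"{v}_{j}" for j in range(p)], vals,
                                       np.ones_like(vals, dtype=bool))
    return LongitudinalDataset(blocks, sample_ids, list(views), list(tps))
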