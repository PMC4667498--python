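import numpy as np
import pytest

from lracluster import (
    OmicsBlock,
    SolverConfig,
    default_spec,
    fit,
    simulate_dataset,
)


def random_block(rng: np.random.Generator, dtype: str, p: int = 6, n: int = 5,
                 with_mask: bool = False) -> OmicsBlock:
    """A small valid block of the given dtype with random contents."""
    if dtype == "gaussian":
        data = rng.standard_normal((p, n)) * 2.0
    elif dtype == "binary":
        data = rng.integers(0, 2, size=(p, n)).astype(float)
    else:
        data = rng.poisson(2.0, size=(p, n)).astype(float)
    mask = rng.random((p, n)) > 0.2 if with_mask else np.ones((p, n), bool)
    if with_mask and not mask.any():
        mask[0, 0] = True
    return OmicsBlock(name=f"{dtype}_test", data=data, dtype=dtype, mask=mask)


@pytest.fixture(scope="session")
def default_dataset():
    """Planted three-block dataset from the default recipe, seed 0."""
    return simulate_dataset(default_spec(0))


@pytest.fixture(scope="session")
def default_fit(default_dataset):
    """Rank-2 fit of the default dataset (shared across tests)."""
    blocks, truth = default_dataset
    return fit(blocks, SolverConfig(rank=2)), blocks, truth
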