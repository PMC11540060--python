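import numpy as np
import pytest

from sgjmda import RunConfig
from sgjmda.fusion import fuse_side
from sgjmda.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def bench():
    """The standard synthetic benchmark: 120 microbes x 20 diseases, rank 4."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size config for fast training tests."""
    return RunConfig(layer_size=32, epochs=50, seed=0)


@pytest.fixture(scope="session")
def fused(bench, small_cfg):
    """Fused feature matrices for both sides of the benchmark."""
    SM = fuse_side(*bench.microbe_similarities, small_cfg)
    SD = fuse_side(*bench.disease_similarities, small_cfg)
    return SM, SD


def random_symmetric(n: int, seed: int = 0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return v
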