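import numpy as np
import pytest

from radpdl1.nn import FTTransformerConfig
from radpdl1.preprocess import preprocess
from radpdl1.synthetic import PhantomSpec, make_phantom
from radpdl1.types import LesionVolume


@pytest.fixture(scope="session")
def small_phantom() -> LesionVolume:
    """A preprocessed textured phantom used across extraction tests."""
    spec = PhantomSpec(grid_shape=(32, 32, 32), radii_mm=(10.0, 9.0, 8.0),
                       heterogeneity=40.0, seed=7)
    return preprocess(make_phantom(spec))


@pytest.fixture(scope="session")
def bench_net_config():
    """Compact transformer configuration for benchmark-scale tests.

    The architecture is the production one scaled down (fewer layers,
    narrower tokens, faster schedule) so statistically meaningful
    multi-seed runs fit in a test session.
    """
    def factory(seed: int = 0, **overrides) -> FTTransformerConfig:
        kw = dict(token_dim=32, n_layers=2, n_heads=4, ffn_multiplier=2,
                  dropout=0.1, learning_rate=1e-3, batch_size=32,
                  max_epochs=60, patience=10, seed=seed)
        kw.update(overrides)
        return FTTransformerConfig(**kw)
    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_droi_arrays(rng, shape=(6, 6, 6), n_levels=5, mask_p=0.85):
    """A random small discretized ROI (levels + mask) for oracle checks."""
    mask = rng.random(shape) < mask_p
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return levels, mask
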