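import numpy as np
import pytest

from hdwm.synthetic_data import (
    EffectSpec,
    PhantomConfig,
    make_cohort,
    make_phantom_tractogram,
    make_protocol,
)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A light phantom: 16^3 grid, 30 streamlines per bundle."""
    return PhantomConfig(grid_shape=(16, 16, 16), voxel_size=2.0,
                         n_streamlines_per_bundle=30, seed=7)


@pytest.fixture(scope="session")
def small_tractogram(small_config):
    return make_phantom_tractogram(small_config)


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced multi-shell protocol keeping all six study shells."""
    return make_protocol(shells={0: 6, 500: 12, 1200: 12, 2400: 15,
                                 4000: 15, 6000: 15})


@pytest.fixture(scope="session")
def small_cohort(small_config, small_tractogram):
    cohort, maps = make_cohort(6, 6, EffectSpec(), small_config,
                               tractogram=small_tractogram)
    return cohort, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
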