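import numpy as np
import pytest

from shgquant import PhantomConfig, generate_phantom
from shgquant.io import max_project, subtract_background


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A modest default-SNR phantom with its ground truth."""
    cfg = PhantomConfig(
        shape=(128, 128),
        n_fibers=8,
        fiber_width_px=3,
        fiber_length_range_px=(40, 90),
        seed=7,
    )
    return cfg, *generate_phantom(cfg)


def projected(cfg, stack):
    """Background-subtracted projection using the generator's true offsets."""
    return subtract_background(
        max_project(stack), "constant", cfg.background_f, cfg.background_b
    )
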