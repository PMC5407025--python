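import numpy as np
import pytest

from vsoptrack import PhantomConfig

# compact grid with the same physical field of view and slice geometry as
# the default phantom; keeps unit tests fast
SMALL_GRID = dict(
    grid_shape=(64, 52, 14),
    voxel_size_mm=(14.0 / 64, 11.0 / 52, 1.0),
    brain_axes_mm=(6.0, 4.8, 6.0),
    lesion_axes_mm=(2.5, 2.0, 2.5),
    lesion_center_mm=(3.0, 0.0, 0.0),
)


@pytest.fixture
def small_config():
    """Factory for fast low-resolution phantom configurations."""

    def make(**overrides):
        kwargs = dict(SMALL_GRID, n_speckles=60, noise_sigma=0.02,
                      bias_amplitude=0.1, seed=0)
        kwargs.update(overrides)
        return PhantomConfig(**kwargs)

    return make


@pytest.fixture
def clean_config(small_config):
    """Small phantom with no speckles, bias or noise."""

    def make(**overrides):
        kwargs = dict(n_speckles=0, bias_amplitude=0.0, noise_sigma=0.0)
        kwargs.update(overrides)
        return small_config(**kwargs)

    return make
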