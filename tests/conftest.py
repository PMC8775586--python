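import numpy as np
import pytest

from mouseview.config import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_config():
    """Config scaled to the small synthetic images used in tests."""
    return PipelineConfig(sigma_list=(5.0, 10.0), acf_offsets=((20, 0), (0, 20)))


@pytest.fixture
def smooth_image(rng):
    """A smooth 96x96 synthetic field in [0, 1] (low-frequency content)."""
    from mouseview.synthetic import spectral_field

    return spectral_field((96, 96), 3.0, rng)
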