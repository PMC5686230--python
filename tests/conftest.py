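import numpy as np
import pytest

from wsicyto.synthetic import generate_slide, immune_config


@pytest.fixture(scope="session")
def small_immune_slide():
    """A small but fully populated immune-panel slide pair with truth."""
    cfg = immune_config(image_height_px=1280, image_width_px=1280,
                        gland_axes=(60, 120), rng_seed=3)
    fl, bf, truth = generate_slide(cfg)
    return cfg, fl, bf, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
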