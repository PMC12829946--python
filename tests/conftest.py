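import logging

import numpy as np
import pytest

from predscan import synthetic_data as synth
from predscan.types import ReceptiveField, StimulusImage

logging.getLogger("predscan").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_images():
    """Eight mixed 128x128 stimuli spanning the full 120-degree field."""
    return synth.gen_images(8, "mixed", 128, 120.0 / 128, seed=11)


@pytest.fixture(scope="session")
def central_rf():
    """Circular RF comfortably inside a 120-degree field."""
    return ReceptiveField(center_x=60.0, center_y=60.0, sigma_x=6.5, sigma_y=6.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grating_image():
    n = 128
    dpp = 120.0 / n
    ys, xs = np.mgrid[0:n, 0:n]
    # 0.08 cpd vertical grating: third CE scale, orientation 0
    px = 0.5 + 0.5 * np.sin(2 * np.pi * 0.08 * dpp * xs)
    return StimulusImage(px, dpp)
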