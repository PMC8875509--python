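import numpy as np
import pytest

from smlm_iccs import LocalizationTable, RenderedImage


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_table():
    """Two-channel toy table with 6 events over 4 frames."""
    return LocalizationTable.from_arrays(
        frame=[0, 1, 2, 3, 0, 2],
        x=[100.0, 200.0, 300.0, 400.0, 150.0, 250.0],
        y=[110.0, 210.0, 310.0, 410.0, 160.0, 260.0],
        channel=["ch1", "ch1", "ch1", "ch2", "ch2", "ch2"],
        photons=[1000.0, 1100.0, 900.0, 1200.0, 800.0, 950.0],
        n_frames=4,
    )


def random_image_pair(rng, shape=(12, 14), pixel_size=10.0):
    a = RenderedImage(rng.random(shape), pixel_size, (0.0, 0.0), 50.0)
    b = RenderedImage(rng.random(shape), pixel_size, (0.0, 0.0), 50.0)
    return a, b
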