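import numpy as np
import pytest

from morphatlas import synthetic as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """32³ blob at 2 µm spacing with 7 landmarks (shared, read-only)."""
    label, marks = syn.make_phantom(
        syn.PhantomSpec(
            shape=(32, 32, 32), radii_frac=(0.20, 0.24, 0.22), lobe_offset_frac=0.20, seed=5
        )
    )
    return label, marks


def gaussian_blob(shift=(0.0, 0.0), n=64, widths=(10.0, 14.0)):
    """Smooth 2D test image: anisotropic Gaussian blob, peak 1."""
    x, y = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return np.exp(
        -(((x - n / 2 - shift[0]) / widths[0]) ** 2 + ((y - n / 2 - shift[1]) / widths[1]) ** 2)
    )
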