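import numpy as np
import pytest

from strain2scar.bullseye import BullseyeLayout, circular_roi
from strain2scar.phantoms import PhantomSpec, generate_strain_field


@pytest.fixture(scope="session")
def layout64():
    return BullseyeLayout(resolution=64)


@pytest.fixture(scope="session")
def layout128():
    return BullseyeLayout(resolution=128)


@pytest.fixture(scope="session")
def roi128(layout128):
    return circular_roi(layout128)


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(infarct_center=(1, 1.0), infarct_fraction=0.20,
                       stiffness_scale=1.0, noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noiseless_field(noiseless_spec, layout128):
    return generate_strain_field(noiseless_spec, layout128)


@pytest.fixture(scope="session")
def smooth_test_image():
    """Band-limited random texture: smooth but with gradients everywhere."""
    from scipy import ndimage
    rng = np.random.default_rng(11)
    img = ndimage.gaussian_filter(rng.standard_normal((96, 96)), 3.0)
    return (img - img.min()) / (img.max() - img.min())
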