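import warnings

import numpy as np
import pytest

from braincad import PhantomSpec, generate_phantom

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tumor_phantom():
    """One pathological phantom with a single tumor, fixed seed."""
    return generate_phantom(PhantomSpec(n_tumors=1, seed=7))


@pytest.fixture(scope="session")
def healthy_phantom():
    return generate_phantom(PhantomSpec(n_tumors=0, seed=7))


@pytest.fixture(scope="session")
def texture_patch():
    """Seeded smooth random texture, 64x64 uint8, for descriptor tests."""
    from scipy import ndimage

    r = np.random.default_rng(99)
    field = ndimage.gaussian_filter(r.standard_normal((64, 64)), 2.0)
    field = (field - field.min()) / (field.max() - field.min())
    return np.round(field * 255).astype(np.uint8)
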