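import numpy as np
import pytest

from zot.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def disk_phantom():
    """Noisy disk phantom at the default study conditions (4 mm band, 5% noise)."""
    return make_phantom(PhantomSpec(seed=1, noise_sd=2.0))


@pytest.fixture(scope="session")
def clean_disk_phantom():
    """Noiseless disk phantom: the geometry-only reference case."""
    return make_phantom(PhantomSpec(seed=1, noise_sd=0.0))


@pytest.fixture(scope="session")
def disk_mask():
    yy, xx = np.mgrid[0:64, 0:64]
    return np.hypot(yy - 31.5, xx - 31.5) <= 20
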