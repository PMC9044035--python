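import numpy as np
import pytest

from hsileaf import Hypercube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cube_factory():
    """Build small reflectance cubes with a uniform wavelength grid."""

    def make(values=None, shape=(4, 4, 3), scale="fraction", wavelengths=None,
             seed=0):
        if values is None:
            values = np.random.default_rng(seed).uniform(0.0, 1.0, size=shape)
        values = np.asarray(values, dtype=np.float32)
        if wavelengths is None:
            wavelengths = np.linspace(468.0, 898.0, values.shape[2])
        return Hypercube(values, wavelengths, scale)

    return make
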