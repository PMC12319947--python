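import numpy as np
import pytest

from neurogsp.graph import eigendecompose, normalized_laplacian
from neurogsp.gsp import RegionTimeSeries
from neurogsp.synthetic import make_connectome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_connectome():
    """A connected 16-region geometric connectome."""
    return make_connectome(16, density=0.4, seed=7)


@pytest.fixture(scope="session")
def small_spectrum(small_connectome):
    return eigendecompose(normalized_laplacian(small_connectome))


@pytest.fixture
def random_signal(small_spectrum, rng):
    values = rng.standard_normal((small_spectrum.n_modes, 64))
    return RegionTimeSeries(values=values, sampling_rate=32.0, subject_id="s0")
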