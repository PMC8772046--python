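import numpy as np
import pytest

from tglrr.solver import TGLRRParams, fit_tglrr
from tglrr.synthetic import SyntheticSpec, make_subspace_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_fixture():
    """Modest 3-subspace dataset used by several solver-level tests."""
    spec = SyntheticSpec(
        n_clusters=3,
        subspace_dim=3,
        samples_per_cluster=(15, 15, 15),
        ambient_dim=60,
        noise_sigma=0.05,
        corruption_frac=0.01,
        seed=7,
    )
    return make_subspace_data(spec)


@pytest.fixture(scope="session")
def small_fit(small_fixture):
    params = TGLRRParams(max_iter=300)
    return fit_tglrr(small_fixture.X, params)
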