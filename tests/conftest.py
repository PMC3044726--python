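import numpy as np
import pytest

from natscreen.synthetic_data import make_query_poses, reference_complex


@pytest.fixture(scope="session")
def complex_fixture():
    return reference_complex()


@pytest.fixture(scope="session")
def model(complex_fixture):
    return complex_fixture.model


@pytest.fixture(scope="session")
def receptor(complex_fixture):
    return complex_fixture.receptor


@pytest.fixture(scope="session")
def template(complex_fixture):
    return complex_fixture.template


@pytest.fixture(scope="session")
def query_poses(model):
    return make_query_poses(model, n_queries=3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=rng).as_matrix()
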