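import numpy as np
import pytest

from radshape import PointCloud, make_template


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cloud():
    return PointCloud(points=np.array(
        [[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]))


@pytest.fixture(scope="session")
def template():
    """Medium-resolution stylized bone shared across tests."""
    cloud, landmarks, facet = make_template(800, seed=7)
    return cloud, landmarks, facet
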