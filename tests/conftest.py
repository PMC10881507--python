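import numpy as np
import pytest

from marmotrack.geometry import CageModel, default_camera_rig


@pytest.fixture(scope="session")
def cage():
    return CageModel()


@pytest.fixture(scope="session")
def rig(cage):
    return default_camera_rig(cage)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_interior_points(rng, cage, n, margin=100.0):
    lo = np.full(3, margin)
    hi = np.array([cage.width, cage.depth, cage.height]) - margin
    return rng.uniform(lo, hi, size=(n, 3))
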