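import numpy as np
import pytest

from tarpose import BiplanarRig, Pose
from tarpose.synthetic import make_implant_mesh


@pytest.fixture(scope="session")
def rig():
    return BiplanarRig()


@pytest.fixture(scope="session")
def tibial_mesh():
    return make_implant_mesh("tibial", asymmetric=True)


@pytest.fixture(scope="session")
def symmetric_tibial_mesh():
    return make_implant_mesh("tibial", asymmetric=False)


@pytest.fixture(scope="session")
def talar_mesh():
    return make_implant_mesh("talar")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_pose(rng, rot=10.0, trans=5.0):
    p = np.concatenate([rng.uniform(-rot, rot, 3), rng.uniform(-trans, trans, 3)])
    return Pose(*p)
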