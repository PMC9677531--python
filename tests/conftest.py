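import numpy as np
import pytest

from mbt.kernel import build_default_kernel
from mbt.nuclide import RadionuclideSpec, Suspension
from mbt.planner import greedy_plan
from mbt.synthetic import sphere_phantom


@pytest.fixture(scope="session")
def nuclide():
    return RadionuclideSpec()


@pytest.fixture(scope="session")
def suspension():
    return Suspension()


@pytest.fixture(scope="session")
def kernel():
    return build_default_kernel()


@pytest.fixture(scope="session")
def gtv15():
    """15 mm-diameter spherical GTV at 1 mm isotropic voxels."""
    return sphere_phantom(15.0)


@pytest.fixture(scope="session")
def plan15(gtv15):
    """Default greedy plan on the 15 mm sphere (shared: planning is the slow step)."""
    return greedy_plan(gtv15)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
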