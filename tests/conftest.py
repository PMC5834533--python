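import numpy as np
import pytest

from fhnring.model import DisturbanceSpec, NetworkParams
from fhnring.simulation import default_paper_setup


@pytest.fixture(scope="session")
def paper_setup():
    """The study's default network, controller and simulation configuration."""
    return default_paper_setup()


@pytest.fixture(scope="session")
def network(paper_setup):
    return paper_setup[0]


@pytest.fixture(scope="session")
def controller(paper_setup):
    return paper_setup[1]


@pytest.fixture(scope="session")
def quiet_network(network):
    """The study network with all disturbances switched off."""
    return NetworkParams.from_arrays(
        r=network.r,
        b=network.b,
        g=network.g,
        stimulus=network.stimulus,
        disturbances=tuple(
            DisturbanceSpec(0.0, d.angular_frequency) for d in network.disturbances
        ),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
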