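import numpy as np
import pytest

from radonchamber import load_chain
from radonchamber.kernels import ChainState, SystemParameters


@pytest.fixture(scope="session")
def radon():
    return load_chain("Rn-222")


@pytest.fixture(scope="session")
def thoron():
    return load_chain("Rn-220")


def random_scenario(rng, chain):
    """One randomized chamber scenario: log-uniform volume and inflow, uniform
    device flow and efficiency, random non-negative initial state, and a
    log-uniform query time between 1 s and 30 d."""
    params = SystemParameters(
        V=10 ** rng.uniform(-1, 2),
        E1=10 ** rng.uniform(-2, 2),
        Q_D=rng.uniform(0.0, 100.0) / 60000.0,
        F=rng.uniform(0.0, 1.0),
    )
    state0 = ChainState(rng.uniform(0.0, 1000.0, len(chain)))
    t = 10 ** rng.uniform(0.0, np.log10(30 * 86400.0))
    return params, state0, t
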