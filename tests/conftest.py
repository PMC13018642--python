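import numpy as np
import pytest

import iobntsim as ib


@pytest.fixture(scope="session")
def pk():
    return ib.PKParameters()


@pytest.fixture(scope="session")
def gains():
    return ib.ControlGains()


@pytest.fixture(scope="session")
def policy(pk):
    return ib.default_policy(pk)


@pytest.fixture(scope="session")
def default_forward(pk):
    """Open-loop forward run at defaults (shared across tests)."""
    return ib.simulate_forward(pk, pk.omega_0)


@pytest.fixture(scope="session")
def reverse_params():
    return ib.ReverseParameters()


@pytest.fixture(scope="session")
def closed_loop_reference(pk, gains, policy):
    """Noiseless closed-loop reference at Pc = 0.6 over 24 h."""
    trace = ib.generate_trace("correct", 0.6)
    return ib.run_closed_loop(trace, pk, gains, policy, rtol=1e-6, atol=1e-9)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
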