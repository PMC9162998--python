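import numpy as np
import pytest

import hemoloop as hl


@pytest.fixture(scope="session")
def constants():
    return hl.ModelConstants()


@pytest.fixture(scope="session")
def patient(constants):
    return hl.make_hf_patient(hl.PatientConfig(), constants)


@pytest.fixture(scope="session")
def zero_noise_run(patient):
    """Default 60-min closed loop with measurement noise disabled."""
    return hl.run_closed_loop(
        patient, hl.ProtocolConfig(noise_enabled=False), seed=0
    )


@pytest.fixture(scope="session")
def noisy_run(patient):
    """Default 60-min closed loop, noise on, seed 1."""
    return hl.run_closed_loop(patient, hl.ProtocolConfig(), seed=1)


def random_states(n, seed, constants=None):
    """Feasible random hemodynamic states spanning the physiologic range."""
    c = constants or hl.ModelConstants()
    rng = np.random.default_rng(seed)
    states = []
    while len(states) < n:
        s = hl.HemodynamicState(
            t=0.0,
            AP=rng.uniform(60.0, 130.0),
            CO=rng.uniform(50.0, 200.0),
            P_LA=rng.uniform(c.P0_L + 2.0, 25.0),
            P_RA=rng.uniform(c.P0_R + 1.5, 15.0),
        )
        if s.AP > s.P_RA:
            states.append(s)
    return states
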