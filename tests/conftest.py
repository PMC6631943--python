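import numpy as np
import pytest

import popivivc as pv
from popivivc import defaults


@pytest.fixture(scope="session")
def fdiss():
    """Dog population-mean transit/Hill parameters."""
    return defaults.FDISS


@pytest.fixture(scope="session")
def population():
    return defaults.reference_population()


@pytest.fixture(scope="session")
def rk4_config():
    return pv.SolverConfig(method="rk4")


@pytest.fixture(scope="session")
def typical_ir():
    return defaults.typical_subject("IR")


def mono_exponential_profile(c0=100.0, lam=0.2, times=None, subject="mono", dose=1.0):
    """Exact one-compartment decline, the standard NCA oracle."""
    times = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0]) if times is None else np.asarray(times, float)
    conc = c0 * np.exp(-lam * times)
    return pv.PlasmaProfile(subject, "test", dose, times, conc)
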