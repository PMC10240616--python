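import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fuzzypolar as fp

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mac_net():
    return fp.macrophage_network()


@pytest.fixture(scope="session")
def mac_markers():
    return fp.macrophage_markers()


@pytest.fixture(scope="session")
def mac_system(mac_net):
    return fp.build_ode_system(mac_net)


@pytest.fixture()
def relay_net():
    """Input A feeding a single transcription factor B (rule: A)."""
    return fp.loads_network("A, extracellular, -\nB, tf, A\n")


@pytest.fixture()
def toggle_net():
    """Two-node mutual inhibition: A = NOT B, B = NOT A."""
    return fp.loads_network("A, tf, NOT B\nB, tf, NOT A\n")


@pytest.fixture()
def fast_cfg():
    return fp.SimulationConfig(t_max=100.0, convergence_tol=1e-6)


def steady(q, names, residual=0.0):
    """Hand-built converged SteadyState for labeling tests."""
    from fuzzypolar.dynamics import StateClass, SteadyState

    return SteadyState(
        q=np.asarray(q, dtype=float),
        converged=True,
        residual=residual,
        classification=StateClass.fixed_point,
        names=list(names),
    )
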