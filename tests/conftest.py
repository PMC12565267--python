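import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from coro0d.demo import demo_network, demo_patient
from coro0d.solver import SolverSettings
from coro0d.waveforms import aortic_flow_template, scale_inflow_waveform

hyp_settings.register_profile("ci", derandomize=True, max_examples=30,
                              deadline=None)
hyp_settings.load_profile("ci")


@pytest.fixture(scope="session")
def patient():
    return demo_patient()


@pytest.fixture(scope="session")
def inflow(patient):
    return scale_inflow_waveform(aortic_flow_template(), patient)


@pytest.fixture()
def demo_net():
    return demo_network(55.0)


@pytest.fixture(scope="session")
def fast_settings():
    """Coarser output grid for speed; identical physics."""
    return SolverSettings(time_step=2e-3, max_cycles=16,
                          periodicity_tolerance=1e-3, rtol=1e-5, atol=1e-4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def demo_states(inflow, fast_settings):
    """Rest and hyperemic periodic solves of the demo patient (shared)."""
    from coro0d.solver import run_to_periodic
    from coro0d.tuning import HYPEREMIA, apply_state

    net = demo_network(55.0)
    rest = run_to_periodic(net, inflow, fast_settings, state_label="rest")
    net_h = apply_state(net, HYPEREMIA)
    hyper = run_to_periodic(net_h, inflow, fast_settings, state_label="hyperemia",
                            initial_state=rest.final_state)
    return {"network": net, "rest": rest, "hyper_network": net_h, "hyper": hyper}
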