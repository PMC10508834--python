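import numpy as np
import pytest

import pulmflow as pf


@pytest.fixture(scope="session")
def reference_network():
    return pf.load_reference_network()


@pytest.fixture(scope="session")
def waveforms():
    q, p = pf.default_waveforms(1024, 0.85)
    return pf.BoundaryWaveforms(q_inflow=q, p_la=p, period=0.85)


@pytest.fixture(scope="session")
def nominal_theta():
    return pf.ParameterVector.nominal()


@pytest.fixture(scope="session")
def nominal_solution(reference_network, waveforms, nominal_theta):
    """One converged coarse-grid simulation of the full 27-vessel network."""
    sol = pf.simulate(
        reference_network, nominal_theta, waveforms, pf.SolverConfig.coarse()
    )
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def toy_solution(waveforms, nominal_theta):
    net = pf.make_toy_network(1)
    sol = pf.simulate(net, nominal_theta, waveforms, pf.SolverConfig.coarse())
    assert sol.converged
    return sol


def single_vessel_network(length=20.0, radius=0.5):
    """A lone artery with prescribed inflow and outlet pressure."""
    import pandas as pd

    from pulmflow.geometry import build_proximal_network

    tab = pd.DataFrame(
        [("A1", "artery", length, radius, "", "")],
        columns=["name", "kind", "length_cm", "radius_cm", "parent", "daughters"],
    )
    return build_proximal_network(tab)
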