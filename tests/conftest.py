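import math

import pytest

from cytoclamp import circuit, presets
from cytoclamp.core import VoltageProtocol


@pytest.fixture(scope="session")
def shsy5y():
    return presets.load_circuit_preset("shsy5y")


@pytest.fixture(scope="session")
def hek293():
    return presets.load_circuit_preset("hek293")


@pytest.fixture(scope="session")
def extracellular():
    return presets.load_recipe("extracellular")


@pytest.fixture(scope="session")
def intracellular():
    return presets.load_recipe("intracellular")


@pytest.fixture
def passive_cell():
    """A whole-cell circuit with every ionic branch switched out."""
    return circuit.CircuitParameters(
        r_seal_mohm=math.inf,
        r_access_mohm=10.0,
        c_m_pf=30.0,
        c_pipette_pf=0.0,
        switches=circuit.SwitchState(s_k=False, s_na=False, s_other=False),
    )


@pytest.fixture
def test_pulse_protocol():
    return VoltageProtocol(((0.0, 5.0), (20.0, 10.0), (0.0, 5.0)))
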