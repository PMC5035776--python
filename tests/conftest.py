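import numpy as np
import pytest

from sbcsim.model import (CompartmentModel, Compartment, ChannelSpec,
                          SimulationConfig, build_default_sbc)


@pytest.fixture(scope="session")
def default_model():
    return build_default_sbc()


@pytest.fixture
def leak_only_model():
    """Single passive compartment: 14.5 nS leak at -65 mV, 20.1 pF."""
    soma = Compartment(label="soma", c_pF=20.1, g_leak_nS=14.5, channels=[])
    return CompartmentModel(compartments=[soma], leak_e_rev_mV=-65.0,
                            axial_g_nS=[])


@pytest.fixture
def short_cfg():
    return SimulationConfig(dt=1e-5, duration=0.05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
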