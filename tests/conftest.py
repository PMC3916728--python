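import numpy as np
import pytest

from ephapsim import (ChannelSet, DiscretizationConfig, PassiveSpec,
                      build_membrane, ca3_passive, discretize,
                      generate_morphology, read_swc, uniform_cylinder)
from ephapsim.runner import build_model
from ephapsim.synthetic import ca3_like_config

MINIMAL_SWC = """# soma root + two dendrite points
1 1 0 0 0 5 -1
2 3 10 0 0 0.3 1
3 3 20 0 0 0.3 2
"""


@pytest.fixture(scope="session")
def ca3_tree():
    return read_swc(generate_morphology(ca3_like_config(0)))


@pytest.fixture(scope="session")
def ca3_model(ca3_tree):
    p = ca3_passive()
    return discretize(ca3_tree, DiscretizationConfig(Ra=p.Ra, Cm=p.Cm))


@pytest.fixture(scope="session")
def ca3_membrane():
    return build_model("ca3", 0)


@pytest.fixture(scope="session")
def ca1_membrane():
    return build_model("ca1", 0)


@pytest.fixture(scope="session")
def passive_cylinder():
    """30-compartment passive cylinder membrane (e_pas = -65 mV)."""
    model = uniform_cylinder(30, 600.0, 1.0)
    return build_membrane(model, ChannelSet("passive", []),
                          PassiveSpec(tau_m=28.0, Rm=28.0, Ra=150.0, Cm=1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
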