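import numpy as np
import pytest

from kernelfield.cable import make_cell
from kernelfield.membrane import LeakSpec
from kernelfield.morphology import SectionSpec, build_ball_and_sticks, preset_sections


@pytest.fixture
def toy_cell():
    """Single passive compartment: g_L = 5e-5 S/cm2, E_L = -70, 30x30 um soma."""
    geom = build_ball_and_sticks([SectionSpec("soma", 30.0, 30.0, 1)])
    return make_cell(geom, LeakSpec(g_L=5e-5, E_L=-70.0))


@pytest.fixture
def e_geometry():
    return build_ball_and_sticks(preset_sections("E"))


@pytest.fixture
def e_cell(e_geometry):
    """Passive ball-and-sticks excitatory preset with section-wise leak."""
    leak = {
        "soma": LeakSpec(g_L=0.0000338, E_L=-90.0),
        "apic": LeakSpec(g_L=0.0000589, E_L=-90.0),
        "basal": LeakSpec(g_L=0.0000589, E_L=-90.0),
    }
    return make_cell(e_geometry, leak, R_a=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_net():
    """Scaled-down two-population reference network used by oracle tests."""
    from dataclasses import replace

    from kernelfield.netspec import reference_network

    net = reference_network(N_E=64, N_I=16)
    net.connections = {k: replace(c, C=0.2) for k, c in net.connections.items()}
    return net
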