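import numpy as np
import pytest

from neuroenergy.dynamics import SimulationSettings, simulate_single
from neuroenergy.graphs import DirectedGraph, draw_stimulus, generate_er


@pytest.fixture(scope="session")
def single_traj():
    """One HH neuron, I = 20 uA, 100 ms, dt = 0.01 ms, full recording."""
    return simulate_single(20.0, SimulationSettings(dt=0.01, duration=100.0))


@pytest.fixture(scope="session")
def small_graph():
    """A 30-neuron ER graph at connectome-like density."""
    return generate_er(30, 120, seed=5)


@pytest.fixture(scope="session")
def small_stimulus():
    return draw_stimulus(30, 7.0, 30.0, seed=6)
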