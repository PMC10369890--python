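import numpy as np
import pytest

from dmsdelta import ScenarioConfig, SimulationConfig, make_reference


@pytest.fixture
def small_ref():
    """A 400-nt uniform-composition reference, fixed seed."""
    return make_reference(400, seed=11)


@pytest.fixture
def small_cfg():
    """Desk-scale simulation config: shallow depth, default chemistry."""
    return SimulationConfig(read_depth=2000, rng_seed=7)


@pytest.fixture
def small_scenario():
    """A reduced scenario (600-nt reference, shallow depth) for fast
    end-to-end runs where calling accuracy is not under test."""
    scn = ScenarioConfig(ref_length=600, n_up=3, n_down=1)
    scn.sim.read_depth = 20_000
    return scn


@pytest.fixture
def rng():
    return np.random.default_rng(123)
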