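import numpy as np
import pytest

from multistress.null_models import StressCapacity
from multistress import simulation_study as ss


@pytest.fixture(scope="session")
def capacity():
    return StressCapacity()


@pytest.fixture(scope="session")
def full_grid_results():
    """The full default simulation grid (250,000 conditions), run once."""
    return ss.run_simulation(ss.build_grid())


@pytest.fixture(scope="session")
def small_grid_results():
    """A coarse two-shape grid for cheap structural checks."""
    return ss.run_simulation(ss.build_grid(0.1, ["linear", "accelerating"]))
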