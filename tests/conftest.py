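import numpy as np
import pytest

from clpnet import default_ground_truth, simulate_panel
from clpnet.synthetic import apply_attrition


@pytest.fixture(scope="session")
def small_panel():
    """Fully observed 3-wave panel from the study-emulating spec."""
    spec = default_ground_truth(seed=7, n_waves=3)
    return simulate_panel(spec, 800, seed=7)


@pytest.fixture(scope="session")
def attrited_panel():
    """5-wave panel with monotone MAR attrition applied."""
    spec = default_ground_truth(seed=11, n_waves=5)
    panel = simulate_panel(spec, 1200, seed=11)
    return apply_attrition(panel, spec, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
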