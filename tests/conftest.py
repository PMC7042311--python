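import numpy as np
import pytest

from mutdist.distances import SampleProfile
from mutdist.simulate import SimConfig, simulate_tissue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tissue():
    """A deterministic 2000-cell well-mixed tissue shared across tests."""
    return simulate_tissue(SimConfig(muL=5.0, beta=0.9, target_cells=2000, seed=7))


@pytest.fixture
def toy_profiles():
    return [
        SampleProfile("A", frozenset({"a", "b", "c"})),
        SampleProfile("B", frozenset({"b", "c", "d", "e"})),
    ]
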