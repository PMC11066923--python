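import numpy as np
import pytest

from mbdecoda import SimulationDesign, simulate


@pytest.fixture(scope="session")
def zinb_dataset():
    """One moderate seeded dataset from the standard study design."""
    return simulate(SimulationDesign(n=50, K=60, pi=0.2, eta=0.3, phi=3.0, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
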