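import numpy as np
import pytest

from promnuc.simulate import SimConfig, simulate_all


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale synthetic study (500 promoters per class) shared by the
    recovery-style tests."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A small, fast synthetic study for structural tests."""
    return simulate_all(SimConfig(seed=7, n_broad=40, n_peak=40, chrom_length=400_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
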