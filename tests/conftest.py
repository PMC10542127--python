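import numpy as np
import pytest

from myoimmune.simulate import SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study shared by read-only tests."""
    cfg = SimConfig(seed=11, cells_per_donor=300, n_genes=120, n_clusters=6)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
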