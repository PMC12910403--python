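import numpy as np
import pytest

from multigrn import SimConfig, simulate


@pytest.fixture(scope="session")
def small_cfg():
    """A compact multiome: 4 subtypes x 3 conditions x 30 cells."""
    return SimConfig(
        n_cells_per_subtype_per_condition=30,
        n_genes=300,
        n_peaks=400,
        n_dap_per_condition=50,
        n_markers_per_subtype=10,
        planted_targets_per_tf=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
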