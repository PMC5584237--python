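import numpy as np
import pandas as pd
import pytest

from lncmeth.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study used by tests that only need structure."""
    return SimulationConfig(
        seed=7,
        n_tumor=20,
        n_normal=10,
        n_lnc=60,
        n_gene=100,
        n_mirna=60,
        n_probe=600,
        n_high_up=5,
        n_high_down=5,
        n_low_up=5,
        n_low_down=5,
        pairs_per_lnc=2,
        module_size=4,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One study at the default conditions, shared across tests."""
    return simulate_all(SimulationConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_group_series():
    def make(n_tumor, n_normal):
        idx = [f"T{i}" for i in range(n_tumor)] + [f"N{i}" for i in range(n_normal)]
        return pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=idx)

    return make
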