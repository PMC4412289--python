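import numpy as np
import pytest

from cistrans.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete dataset: 4 strains, 2 crosses, induction plus
    cis/trans architecture, injected SNP artifacts."""
    config = SimConfig(
        n_genes=300,
        strains=("B6", "129", "CAST", "NOD"),
        cross_fathers=("129", "CAST"),
        library_size=3e5,
        f1_library_size=1.5e5,
        seed=101,
    )
    return simulate_dataset(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
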