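import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from vitnet.synthetic_data import SimConfig, simulate  # noqa: E402


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast unit tests."""
    return simulate(
        SimConfig(
            seed=5,
            n_loci=3,
            locus_length=300,
            n_panel_snps=120,
            n_other_snps=60,
            locus_dropout=0.0,
        )
    )
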