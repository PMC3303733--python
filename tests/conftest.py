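import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from h2hscan.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_synth():
    """A small but complete synthetic study shared across tests."""
    cfg = SynthConfig(
        seed=11, n_chroms=2, genes_per_chrom=40,
        n_datasets=4, samples_per_dataset=30,
    )
    return generate_dataset(cfg)
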