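import numpy as np
import pytest

from secircuit.synthetic_data import SimConfig


@pytest.fixture
def small_config():
    """Desk-scale config: 30 genes, 4 SEs, 10 TEs on ~1.9 Mb."""
    return SimConfig(
        genome_length=30 * 64_000,
        n_genes=30,
        n_se=4,
        n_te=10,
        n_crc_tfs=2,
        n_decoy_tfs=2,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
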