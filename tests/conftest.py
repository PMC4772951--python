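import numpy as np
import pytest

from mirmotif import MIR10B, SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def mirna():
    return MIR10B


@pytest.fixture(scope="session")
def small_dataset():
    """A modest planted dataset shared by read-only tests."""
    cfg = SynthConfig(
        seed=7,
        n_genes=150,
        isoforms_per_gene=(1, 2),
        frac_up=0.2,
        frac_down=0.2,
        n_switch_genes=10,
    )
    annotation, truth, matrix, samples = generate_dataset(cfg)
    return cfg, annotation, truth, matrix, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
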