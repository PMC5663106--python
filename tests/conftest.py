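import numpy as np
import pytest

from planticlip import synthetic_data as sd


@pytest.fixture(scope="session")
def small_annotation():
    """Four synthetic genes (alternating strands) with full region structure."""
    return sd.make_genome_and_annotation(n_genes=4, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
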