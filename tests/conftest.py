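import numpy as np
import pytest

from epiatlas.genome import GenomeAssembly, bin_genome


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly(("chr1", "chr2"), (1000, 600))


@pytest.fixture
def toy_bins(toy_assembly):
    return bin_genome(toy_assembly, 200)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
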