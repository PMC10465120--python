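import numpy as np
import pytest

from genomni import LatentDistribution


@pytest.fixture(scope="session")
def two_block_mixture() -> LatentDistribution:
    """Balanced two-community blockmodel mixture with Gram matrix
    [[0.7, 0.3], [0.3, 0.5]] — the workhorse simulation model."""
    return LatentDistribution.from_gram(np.array([[0.7, 0.3], [0.3, 0.5]]))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
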