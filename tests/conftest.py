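import numpy as np
import pytest

from admixnet import paper_like_demography, sample_counts, simulate_frequencies


@pytest.fixture(scope="session")
def demo():
    return paper_like_demography()


@pytest.fixture(scope="session")
def demo_table(demo):
    """Sampled frequency table under the bundled admixed demography."""
    table = simulate_frequencies(demo, 5000, seed=20_001, counts=200.0)
    return sample_counts(table, seed=20_002)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
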