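import numpy as np
import pytest

from aquapred import SynthConfig, encode_matrix, gen_benchmark


@pytest.fixture(scope="session")
def small_benchmark_matrix():
    """Encoded synthetic benchmark, small enough for fast CV tests."""
    records, _ = gen_benchmark(SynthConfig(n_pos=60, n_neg=60, seed=11))
    return encode_matrix(records)


@pytest.fixture(scope="session")
def default_benchmark_matrix():
    """Encoded synthetic benchmark at the default study size (150+150)."""
    records, _ = gen_benchmark(SynthConfig(seed=0))
    return encode_matrix(records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
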