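import numpy as np
import pytest

from embedhdp import HdpParams, MetricConfig, make_hash_backend


@pytest.fixture(scope="session")
def stub16():
    """Small stub backend used by the pinned-seed regression tests."""
    return make_hash_backend(dim=16, seed=42)


@pytest.fixture(scope="session")
def stub64():
    """Default-size stub backend for benchmark-style tests."""
    return make_hash_backend(dim=64, seed=0)


@pytest.fixture(scope="session")
def cfg42():
    """Metric configuration with the pinned HDP seed."""
    return MetricConfig(hdp=HdpParams(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_sentence(rng: np.random.Generator, n_tokens: int, pool: int = 20) -> str:
    """Whitespace-joined synthetic sentence over a small token pool."""
    return " ".join(f"g{i:02d}" for i in rng.integers(0, pool, n_tokens))
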