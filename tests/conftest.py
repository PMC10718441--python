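import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from scalestats import GeneratorConfig, filter_corpus, generate_corpus

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_corpus():
    """Synthetic corpus under generator defaults (150 scales, 30 societies)."""
    return generate_corpus(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def measured_corpus(default_corpus):
    return filter_corpus(default_corpus, kind="measured")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
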