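import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stage1_bench():
    """Shared 20 ms two-state benchmark (session-scoped: the mixture fit is
    reused by several tests)."""
    from chromodyn.simulate import make_benchmark_suite

    return make_benchmark_suite("stage1_20ms", seed=11, n_tracks=200, n_frames=31)


@pytest.fixture(scope="session")
def toy_genome():
    from chromodyn.toygenome import make_toy_genome

    return make_toy_genome(seed=5)
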