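import pytest

from vectorfree.simulate import make_host_genome, make_vector


@pytest.fixture(scope="session")
def vector():
    return make_vector(2000, 3000, seed=2)


@pytest.fixture(scope="session")
def small_vector():
    return make_vector(500, 500, seed=3)


@pytest.fixture(scope="session")
def host():
    return make_host_genome(10_000, 0.5, seed=4)
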