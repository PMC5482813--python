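import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from intronfun import phylo

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tree28():
    return phylo.default_tree()


@pytest.fixture(scope="session")
def clades28(tree28):
    return phylo.default_clades(tree28)


@pytest.fixture(scope="session")
def toy_tree():
    # ((A:1,B:1):1,C:2); root age 2, internal node age 1
    return phylo.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
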