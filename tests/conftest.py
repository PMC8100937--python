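import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fitradeoff import normalize_matrix, ranking_space, samu_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def samu():
    return samu_fixture()


@pytest.fixture(scope="session")
def samu_values(samu):
    return normalize_matrix(samu.matrix)


@pytest.fixture(scope="session")
def samu_space(samu):
    return ranking_space(samu.matrix.n_criteria, rank_order=samu.matrix.rank_order())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
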