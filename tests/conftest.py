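import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_library():
    from phagescreen.simulate import make_ag_library

    return make_ag_library(20, seed=11)


@pytest.fixture(scope="session")
def tn5_reference():
    from phagescreen.simulate import make_tn5_reference

    return make_tn5_reference(
        genome_len=20_000, n_genes=20, n_insertions=100, seed=7, gene_len=500
    )
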