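import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from strucfind.backends import NaiveBackend
from strucfind.fixtures import simulate_genomes, simulate_pulldown, simulate_reverse_db
from strucfind.orthology import run_orthology

settings.register_profile(
    "suite", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")

DEFAULT_SEED = 0


@pytest.fixture(scope="session")
def reverse_db():
    """Default reverse-db fixture: 12 pseudo-species, 4 planted families."""
    return simulate_reverse_db(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def genome_fixture():
    return simulate_genomes(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def pulldown():
    return simulate_pulldown(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def orthology_runs(genome_fixture):
    """Iterative and static orthology calls on the gradient fixture.

    Computed once per session: the two modes are compared by several
    tests and each run costs seconds on the naive backend.
    """
    fx = genome_fixture
    backend = NaiveBackend()
    iterative = run_orthology(fx.seed_sets, fx.genomes, backend, fx.references, fx.expected)
    static = run_orthology(
        fx.seed_sets, fx.genomes, backend, fx.references, fx.expected, incorporate=False
    )
    return {"iterative": iterative, "static": static}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
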