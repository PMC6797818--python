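import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from semtraj.synth import CohortConfig, generate_cohort, make_fixture_space
from semtraj.transcript import ExclusionLists

WORDS = [
    "book", "read", "page", "paper", "leather", "grapefruit", "orange",
    "skin", "florida", "produce", "often", "like", "bed", "sleep", "pillow",
    "dolphin", "ocean", "gray", "smart", "mammal",
]


@pytest.fixture(scope="session")
def fixture_space():
    return make_fixture_space(WORDS, dims=16, seed=1)


@pytest.fixture(scope="session")
def exclusions():
    return ExclusionLists.from_profile("extended")


@pytest.fixture(scope="session")
def strict_exclusions():
    return ExclusionLists.from_profile("strict")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but non-trivial simulated cohort shared across tests."""
    cfg = CohortConfig(n_hp=3, n_co=6, n_targets=6)
    trials, space, truth = generate_cohort(cfg, seed=99)
    return trials, space, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
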