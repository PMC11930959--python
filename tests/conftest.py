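import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from riboworld import (
    Chemistry,
    ChemistryParams,
    Folder,
    NussinovBackend,
    RuleTable,
    vienna_available,
)


@pytest.fixture(scope="session")
def rules3() -> RuleTable:
    return RuleTable.default(3)


@pytest.fixture(scope="session")
def rules7() -> RuleTable:
    return RuleTable.default(7)


@pytest.fixture(scope="session")
def params() -> ChemistryParams:
    return ChemistryParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def nussinov_folder() -> Folder:
    return Folder(NussinovBackend())


@pytest.fixture(scope="session")
def chem3() -> Chemistry:
    """Default-backend chemistry with a 3-activity metabolism."""
    return Chemistry(RuleTable.default(3))


@pytest.fixture(scope="session")
def chem7() -> Chemistry:
    return Chemistry(RuleTable.default(7))


@pytest.fixture(scope="session")
def chem3_nussinov() -> Chemistry:
    return Chemistry(RuleTable.default(3), folder=Folder(NussinovBackend()))


@pytest.fixture(scope="session")
def complete_community(chem3):
    """One replicator per activity (A = 3), scanned from a random pool."""
    from riboworld.pool import random_pool

    rng = np.random.default_rng(2024)
    pool = random_pool(4000, 45.0, chem3, rng)
    members = []
    for slot in range(3):
        found = next(
            (r for r in pool.entries if r.traits.activities[slot] > 0), None
        )
        assert found is not None, f"no strand with activity {slot + 1} in the pool"
        members.append(found)
    return members


def pytest_report_header(config):
    return f"riboworld folding engine available: vienna={vienna_available()}"
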