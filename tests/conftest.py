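import numpy as np
import pytest

from aptwq import (
    AsymParams,
    SaturationProtocol,
    apply_exclusions,
    load_table1_fixture,
)


@pytest.fixture(scope="session")
def protocol():
    return SaturationProtocol()


@pytest.fixture(scope="session")
def asym():
    return AsymParams()


@pytest.fixture(scope="session")
def fixture_cohort():
    """The packaged 26-subject reference cohort (treat as read-only)."""
    return load_table1_fixture()


@pytest.fixture(scope="session")
def final_cohort(fixture_cohort):
    """The 22-subject analysis cohort (16 HGG, 6 LGG) after exclusions."""
    return apply_exclusions(fixture_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(20231109)
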