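import numpy as np
import pytest

from txseq.parameters import DEFAULT_BRACKETS, CandidacySchedule, RateTable
from txseq.synthetic import GeneratorSpec, calibration_fixture, generate_rate_tables


@pytest.fixture(scope="session")
def fixture_table():
    table, _ = calibration_fixture()
    return table


@pytest.fixture(scope="session")
def schedule():
    return CandidacySchedule()


@pytest.fixture
def zero_table():
    """All rates zero: immortal cohort, no transitions except certain LD receipt."""
    zeros = np.zeros(len(DEFAULT_BRACKETS))
    return RateTable(
        age_brackets=DEFAULT_BRACKETS,
        dialysis_mortality=zeros.copy(),
        graft_mortality=zeros.copy(),
        graft_failure_LD=zeros.copy(),
        graft_failure_DD=zeros.copy(),
        tx_rate_DD_pediatric=0.0,
        tx_rate_DD_adult=0.0,
        tx_rate_third=0.0,
    )


@pytest.fixture
def random_tables():
    """Small batch of structurally valid randomized tables."""
    return [generate_rate_tables(GeneratorSpec(seed=s)) for s in range(3)]
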