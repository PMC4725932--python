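import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


from aphidfit.lifetable import Cohort, IndividualRecord  # noqa: E402


def make_individual(ind_id, adult_entry, death_age, offspring_by_age=None, stages=None):
    """Build a valid IndividualRecord with minimal bookkeeping.

    ``offspring_by_age`` maps age -> count (defaults empty); nymphal stage
    entries between N1 and Adult are spread evenly unless given.
    """
    entries = {"N1": 0}
    if stages:
        entries.update(stages)
    if adult_entry is not None and adult_entry <= death_age:
        entries["Adult"] = adult_entry
    daily = [0] * (death_age + 1)
    for age, count in (offspring_by_age or {}).items():
        daily[age] = count
    return IndividualRecord(
        individual_id=str(ind_id),
        stage_entry_age=entries,
        death_age=death_age,
        daily_offspring=tuple(daily),
    )


@pytest.fixture
def two_individual_cohort():
    """A dies age 1 with offspring [0, 2]; B dies age 3 with offspring [0, 0, 4, 0]."""
    return Cohort(
        records=(
            make_individual("A", 1, 1, {1: 2}),
            make_individual("B", 2, 3, {2: 4}),
        ),
        host_label="fixture",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
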