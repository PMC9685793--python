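import datetime as dt

import pytest

from rxregimen.cohort import CohortMember
from rxregimen.duration import PrescriptionWithDuration

INDEX = dt.date(2000, 3, 1)


def make_member(
    person_id="P1",
    index=INDEX,
    followup_days=730,
    followup_end=None,
    **overrides,
):
    """A cohort member anchored at a fixed index date, in day offsets."""
    fields = dict(
        person_id=person_id,
        index_date=index,
        followup_end=followup_end or index + dt.timedelta(days=followup_days),
        age_at_index=72.0,
        sex="female",
        first_asm_atc="N03AG01",
        first_diag_icd="G409",
        diag_admit_date=index - dt.timedelta(days=8),
        diag_discharge_date=index - dt.timedelta(days=3),
        hosp_duration_days=5,
        diag_to_first_rx_days=8,
    )
    fields.update(overrides)
    return CohortMember(**fields)


def rx(atc, day, duration, person_id="P1", index=INDEX):
    """A prescription with duration, at a day offset from the index date."""
    return PrescriptionWithDuration(
        person_id=person_id,
        atc=atc,
        redeem_date=index + dt.timedelta(days=day),
        duration_days=duration,
    )


@pytest.fixture
def member():
    return make_member()


@pytest.fixture(scope="session")
def small_registry():
    """A 300-person synthetic registry shared across tests (seed 7)."""
    from rxregimen.synth import SimulationConfig, simulate_registry

    return simulate_registry(SimulationConfig(n_persons=300, seed=7))
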