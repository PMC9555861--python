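"""Schedule generator: printed worked examples, disruption semantics, grid."""

import pytest
from hypothesis import given, settings, strategies as st

from cervisim.scenarios import (
    NO_SCREENS,
    PolicyRules,
    ScenarioSpec,
    build_grid,
    build_schedule,
    last_routine_screen_age,
)


@pytest.mark.parametrize(
    "birth_year, freq, modality, delay, expected_last_age",
    [
        (1975, 10, "CYTOLOGY", 0, 65),
        (1975, 10, "CYTOLOGY", 1, 56),
        (1975, 10, "CYTOLOGY", 2, 57),
        (1975, 10, "CYTOLOGY", 5, 60),
        (1965, 5, "CYTOLOGY", 0, 65),
        (1965, 5, "CYTOLOGY", 1, 61),
    ],
)
def test_last_screen_age_under_delay(birth_year, freq, modality, delay, expected_last_age):
    """Delayed final screens that would pass 65 are dropped, reproducing the
    published last-screen ages for infrequent screeners."""
    schedule = build_schedule(ScenarioSpec(birth_year, freq, modality, delay))
    assert last_routine_screen_age(schedule) == expected_last_age


def test_1975_decennial_screening_ages():
    schedule = build_schedule(ScenarioSpec(1975, 10, "CYTOLOGY", 0))
    post_2010 = [e.age_years for e in schedule.events if e.calendar_year > 2010]
    assert post_2010 == [45, 55, 65]


def test_1985_decennial_hpv_switch():
    """Born 1985, 10-yearly, primary-HPV policy: last pre-2020 screen is the
    age-25 cytology; the switch to HPV happens at the age-35 screen in 2020."""
    schedule = build_schedule(ScenarioSpec(1985, 10, "HPV_PRIMARY", 0))
    pre = [e for e in schedule.events if e.calendar_year < 2020]
    assert pre[-1].age_years == 25 and pre[-1].modality == "CYTOLOGY"
    first_2020 = next(e for e in schedule.events if e.calendar_year >= 2020)
    assert (first_2020.calendar_year, first_2020.age_years, first_2020.modality) == (
        2020, 35, "HPV_PRIMARY",
    )


@pytest.mark.parametrize("birth_year", [1965, 1975, 1985])
@pytest.mark.parametrize("delay", [0, 1, 2, 5])
def test_annual_screeners_keep_final_screen(birth_year, delay):
    """Annual screeners re-reach age 65 after any delay up to 5 years and
    differ from the no-delay schedule only inside/right after the window."""
    base = build_schedule(ScenarioSpec(birth_year, 1, "CYTOLOGY", 0))
    delayed = build_schedule(ScenarioSpec(birth_year, 1, "CYTOLOGY", delay))
    assert last_routine_screen_age(delayed) == 65
    base_years = {e.calendar_year for e in base.events}
    delayed_years = {e.calendar_year for e in delayed.events}
    assert base_years - delayed_years <= set(range(2020, 2020 + delay))


def test_empty_schedule_sentinel():
    schedule = build_schedule(ScenarioSpec.no_screening(1975))
    assert last_routine_screen_age(schedule) == NO_SCREENS
    assert schedule.events == ()


def test_grid_counts():
    specs = build_grid()
    assert len(specs) == 96 + 3
    assert sum(s.is_no_screening for s in specs) == 3
    small = build_grid(cohorts=[1975], frequencies=[3])
    assert len([s for s in small if not s.is_no_screening]) == 8


def test_grid_schedules_satisfy_invariants():
    """Every default-grid schedule: no screen in the delay window, eligible
    ages only, fixed gaps except across the window, screens non-increasing
    and window-nested as delay grows."""
    by_family: dict[str, dict[int, object]] = {}
    for spec in build_grid():
        schedule = build_schedule(spec)
        schedule.validate()  # window emptiness, age bounds, ordering
        years = [e.calendar_year for e in schedule.events]
        for a, b in zip(years, years[1:]):
            if spec.frequency_years and not (a < 2020 <= b):
                assert b - a == spec.frequency_years
        by_family.setdefault(spec.family_id, {})[spec.delay_years] = schedule
    for family, schedules in by_family.items():
        if 0 not in schedules:
            continue
        base_years = {e.calendar_year for e in schedules[0].events}
        n0 = len(schedules[0].events)
        for d, schedule in schedules.items():
            years = {e.calendar_year for e in schedule.events}
            assert len(schedule.events) <= n0 or d == 0
            assert not (years & set(range(2020, 2020 + d)))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    birth_year=st.integers(1950, 1995),
    freq=st.integers(1, 12),
    delay=st.integers(0, 6),
    hpv=st.booleans(),
)
def test_schedule_invariants_property(birth_year, freq, delay, hpv):
    spec = ScenarioSpec(birth_year, freq, "HPV_PRIMARY" if hpv else "CYTOLOGY", delay)
    schedule = build_schedule(spec)
    schedule.validate()
    for e in schedule.events:
        if e.modality == "HPV_PRIMARY":
            assert e.age_years >= spec.policy.hpv_switch_age


def test_policy_rule_validation():
    with pytest.raises(ValueError):
        PolicyRules(start_age=40, hpv_switch_age=30)
    with pytest.raises(ValueError):
        ScenarioSpec(1975, 3, "SELF_SAMPLING")


def test_schedule_frame_export():
    df = build_schedule(ScenarioSpec(1975, 10, "CYTOLOGY", 0)).to_frame()
    assert list(df.columns) == ["cell_id", "calendar_year", "age", "modality"]
    assert len(df) == 5
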