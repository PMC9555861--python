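"""Natural-history engine: one-cycle updates, life courses, dwell times, and
bit-for-bit agreement between the reference driver and the compiled kernel."""

import numpy as np
import pytest

from cervisim.kernel import simulate_cohort
from cervisim.natural_history import (
    WomanRNG,
    dwell_time_summary,
    simulate_life_course,
    step,
)
from cervisim.params import Demography, N_AGES, VaccinationProfile
from cervisim.rng import string_id, woman_key
from cervisim.scenarios import ScenarioSpec, build_schedule
from cervisim.states import DetectionMode, Genotype, HealthState, StateLabel

from conftest import make_params

ZERO_DEM = Demography(np.zeros(N_AGES), np.zeros(N_AGES))


def test_step_no_event_identity():
    p = make_params(
        hpv_incidence_16_18=np.zeros(N_AGES), hpv_incidence_other=np.zeros(N_AGES)
    )
    s, mode = step(HealthState(), 100, p, ZERO_DEM, WomanRNG(42))
    assert s == HealthState() and mode is None


def test_step_forced_symptomatic_detection():
    p = make_params(symptomatic_detection_rate=1.0)
    pc = HealthState(StateLabel.PRECLINICAL_CANCER, Genotype.OTHER_HR)
    s, mode = step(pc, 300, p, ZERO_DEM, WomanRNG(42))
    assert s.label is StateLabel.DIAGNOSED_CANCER
    assert mode is DetectionMode.SYMPTOMATIC
    # ... but never in a cycle with an attended screen
    s, mode = step(pc, 300, p, ZERO_DEM, WomanRNG(42), suppress_symptomatic=True)
    assert s.label is StateLabel.PRECLINICAL_CANCER and mode is None


def test_step_rejects_absorbing_state():
    with pytest.raises(ValueError):
        step(HealthState(StateLabel.DEAD_OTHER), 10, make_params(), ZERO_DEM, WomanRNG(1))


def test_step_clearance_fraction_binomial():
    """One-step clearance frequency from HPV_INFECTED matches the nominal
    0.05/cycle to 3 binomial SE (n = 100,000 independent draws)."""
    p = make_params(
        clearance_16_18=0.05, progression_to_precancer_16_18=0.0,
        hpv_incidence_16_18=np.zeros(N_AGES), hpv_incidence_other=np.zeros(N_AGES),
    )
    inf = HealthState(StateLabel.HPV_INFECTED, Genotype.HPV16_18)
    n = 100_000
    cleared = sum(
        step(inf, 200, p, ZERO_DEM, WomanRNG(woman_key(7, 1, i)))[0].label
        is StateLabel.HEALTHY
        for i in range(n)
    )
    se = np.sqrt(0.05 * 0.95 / n)
    assert abs(cleared / n - 0.05) <= 3 * se


def test_zero_progression_never_diagnosed(demography):
    p = make_params(progression_to_cancer=0.0, symptomatic_detection_rate=0.0)
    schedule = build_schedule(ScenarioSpec(1975, 3, "CYTOLOGY", 0))
    for i in range(200):
        t = simulate_life_course(schedule, p, demography, rng=WomanRNG(woman_key(3, 5, i)))
        assert t.diagnosis is None
        t.validate()


def test_life_course_determinism(medium, demography):
    schedule = build_schedule(ScenarioSpec(1985, 5, "HPV_PRIMARY", 1))
    a = simulate_life_course(schedule, medium, demography, rng=WomanRNG(99))
    b = simulate_life_course(schedule, medium, demography, rng=WomanRNG(99))
    assert a.state_path == b.state_path
    assert a.screen_log == b.screen_log
    assert a.diagnosis == b.diagnosis and a.end == b.end


def test_schedule_outside_life_course_rejected(medium, demography):
    from cervisim.scenarios import Schedule, ScreenEvent

    bad = Schedule(ScenarioSpec(1975, 3, "CYTOLOGY", 0), (ScreenEvent(2065, 90, "CYTOLOGY"),))
    with pytest.raises(ValueError):
        simulate_life_course(bad, medium, demography)


@pytest.mark.parametrize("modality", ["CYTOLOGY", "HPV_PRIMARY"])
def test_kernel_matches_reference_driver(modality, variants, demography):
    """The compiled kernel reproduces the per-woman reference driver
    bit-for-bit (same keys, same draws, same outcomes) on 300 women."""
    p = variants["short_dwell"]  # exercises occult + follow-up paths
    spec = ScenarioSpec(1975, 3, modality, 1)
    schedule = build_schedule(spec)
    n = 300
    sample = simulate_cohort(schedule, p, demography, n=n, master_seed=11)
    family = string_id(spec.family_id)
    for i in range(n):
        t = simulate_life_course(schedule, p, demography, rng=WomanRNG(woman_key(11, family, i)))
        diag_month = t.diagnosis.age_months if t.diagnosis else -1
        mode = -1 if t.diagnosis is None else (
            0 if t.diagnosis.mode is DetectionMode.SYMPTOMATIC else 1
        )
        death = t.end.age_months if t.end.reason == "DEAD_OTHER" else -1
        assert diag_month == sample.diag_month[i]
        assert mode == sample.diag_mode[i]
        assert death == sample.death_month[i]


def test_trajectory_invariants_on_sampled_paths(variants, demography):
    """Sampled trajectories respect the allowed transition edges and
    absorbing-state rules, including paths through occult lesions."""
    p = variants["short_dwell"].replace(occult_fraction=0.5)
    schedule = build_schedule(ScenarioSpec(1965, 3, "CYTOLOGY", 2))
    n_occult = 0
    for i in range(800):
        t = simulate_life_course(schedule, p, demography, rng=WomanRNG(woman_key(21, 2, i)))
        t.validate()
        if any(s.occult for _, s in t.state_path):
            n_occult += 1
    assert n_occult > 5  # occult paths were actually exercised


def test_occult_lesions_invisible_to_cytology_screens(variants, demography):
    """Under pure-cytology screening, occult lesions are never screen-managed:
    with occult fraction forced to 1, no woman is ever treated or surveilled."""
    p = variants["medium_dwell"].replace(occult_fraction=1.0)
    schedule = build_schedule(ScenarioSpec(1975, 1, "CYTOLOGY", 0))
    for i in range(200):
        t = simulate_life_course(schedule, p, demography, rng=WomanRNG(woman_key(31, 4, i)))
        for entry in t.screen_log:
            if entry.get("event") == "SCREEN":
                assert not entry.get("lesion_detected", False)


def test_dwell_time_summary_analytic():
    p = make_params(
        clearance_16_18=0.0, progression_to_precancer_16_18=0.01,
        regression_from_precancer_16_18=0.0, progression_to_cancer=0.01,
        symptomatic_detection_rate=0.02,
    )
    d = dwell_time_summary(p)["16_18"]
    assert d["hpv_to_precancer_months"] == pytest.approx(100.0)
    assert d["precancer_to_preclinical_months"] == pytest.approx(100.0)
    assert d["preclinical_to_symptomatic_months"] == pytest.approx(50.0)
    zero = make_params(symptomatic_detection_rate=0.0)
    assert np.isinf(dwell_time_summary(zero)["other"]["preclinical_to_symptomatic_months"])


def test_dwell_time_empirical_agreement():
    """Mean simulated sojourn (conditional on full progression, no competing
    risks) agrees with the analytic dwell within 3 SE."""
    p = make_params(
        hpv_incidence_16_18=np.zeros(N_AGES), hpv_incidence_other=np.zeros(N_AGES),
        clearance_16_18=0.0, progression_to_precancer_16_18=1 / 24,
        regression_from_precancer_16_18=0.0, progression_to_cancer=1 / 24,
        symptomatic_detection_rate=1 / 12,
    )
    analytic = dwell_time_summary(p)["16_18"]["total_months"]
    n, total, sq = 1500, 0.0, 0.0
    inf = HealthState(StateLabel.HPV_INFECTED, Genotype.HPV16_18)
    for i in range(n):
        rng = WomanRNG(woman_key(17, 9, i))
        state, months = inf, 0
        while state.label is not StateLabel.DIAGNOSED_CANCER:
            state, _ = step(state, months % 1000, p, ZERO_DEM, rng)
            months += 1
            rng = WomanRNG(woman_key(17, 9, i * 2000 + months))  # fresh stream per cycle
        total += months
        sq += months * months
    mean = total / n
    sd = np.sqrt(sq / n - mean**2)
    assert abs(mean - analytic) <= 3 * sd / np.sqrt(n)


def test_vaccination_full_efficacy_blocks_16_18(demography):
    """Full-coverage, full-efficacy vaccination: no HPV16/18 cancers."""
    p = make_params(progression_to_precancer_other=0.0)
    vacc = VaccinationProfile(1985, coverage=1.0, efficacy_16_18=1.0)
    schedule = build_schedule(ScenarioSpec.no_screening(1985))
    sample = simulate_cohort(schedule, p, demography, vacc, n=20_000, master_seed=4)
    assert (sample.diag_month >= 0).sum() == 0
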