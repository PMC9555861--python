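"""Deterministic cohort solver: conservation, closed forms, screening nulls,
vaccination linearity, and agreement with the microsimulation."""

import numpy as np
import pytest

from cervisim.cohort import cohort_solve
from cervisim.kernel import simulate_cohort
from cervisim.outcomes import lifetime_risk, lifetime_risk_se
from cervisim.params import Demography, N_AGES, VaccinationProfile
from cervisim.scenarios import ScenarioSpec, build_schedule
from cervisim.synthetic_params import make_demography

from conftest import closed_form_params, make_params

NOSCREEN_1975 = build_schedule(ScenarioSpec.no_screening(1975))


def test_zero_hazards_zero_risk(no_risk_demography):
    p = make_params(
        hpv_incidence_16_18=np.zeros(N_AGES), hpv_incidence_other=np.zeros(N_AGES)
    )
    sol = cohort_solve(NOSCREEN_1975, p, no_risk_demography)
    assert sol.lifetime_risk == 0.0


def test_occupancy_conserved(medium, demography):
    """State-occupancy mass sums to one at every age (the solver enforces
    1e-10 internally; check the final distribution explicitly too)."""
    sol = cohort_solve(build_schedule(ScenarioSpec(1975, 3, "CYTOLOGY", 1)), medium, demography)
    assert abs(sol.occupancy_final.sum() - 1.0) < 1e-10
    assert np.all(sol.eligible_frac >= 0) and np.all(sol.eligible_frac <= 1)


def test_closed_form_constant_hazard(no_risk_demography):
    """Constant 0.001/yr onset hazard from age 20, no competing risks:
    lifetime risk is exactly 1 - exp(-0.064)."""
    sol = cohort_solve(NOSCREEN_1975, closed_form_params(), no_risk_demography)
    assert sol.lifetime_risk == pytest.approx(1 - np.exp(-0.064), abs=1e-10)


def test_survival_matches_product_limit():
    """With all disease and hysterectomy hazards zero, the solver's survival
    curve equals the life table's product-limit survival."""
    dem0 = make_demography()
    dem = Demography(dem0.life_table, np.zeros(N_AGES))
    p = make_params(
        hpv_incidence_16_18=np.zeros(N_AGES), hpv_incidence_other=np.zeros(N_AGES)
    )
    sol = cohort_solve(NOSCREEN_1975, p, dem)
    death_m, _ = dem.monthly()
    expected = np.concatenate([[1.0], np.cumprod(1.0 - death_m)])
    np.testing.assert_allclose(sol.survival(), expected, atol=1e-12)


def test_non_stochastic_row_rejected(demography):
    p = make_params(hpv_incidence_16_18=np.full(N_AGES, 0.8), hpv_incidence_other=np.full(N_AGES, 0.3))
    with pytest.raises(ValueError, match="sum above 1"):
        cohort_solve(NOSCREEN_1975, p, demography)


def test_zero_sensitivity_screening_equals_no_screening(demography):
    """With every test sensitivity (and false-positive rate) zero, screening
    cells reproduce the no-screening lifetime risk exactly."""
    p = make_params(
        cyto_sens_precancer=0.0, cyto_sens_cancer=0.0, cyto_spec=1.0,
        hpv_sens=0.0, hpv_spec=1.0,
    )
    base = cohort_solve(NOSCREEN_1975, p, demography).lifetime_risk
    for modality in ("CYTOLOGY", "HPV_PRIMARY"):
        sol = cohort_solve(build_schedule(ScenarioSpec(1975, 3, modality, 0)), p, demography)
        assert sol.lifetime_risk == pytest.approx(base, abs=1e-14)


def test_vaccination_linearity_and_blocking(demography):
    """Coverage 0.4 with full 16/18 efficacy removes exactly 40% of the
    16/18-attributed risk; full coverage removes all of it."""
    p = make_params()
    base = cohort_solve(NOSCREEN_1975, p, demography)
    vacc = cohort_solve(
        NOSCREEN_1975, p, demography, VaccinationProfile(1975, coverage=0.4, efficacy_16_18=1.0)
    )
    g0 = base.lifetime_risk_by_genotype()
    g1 = vacc.lifetime_risk_by_genotype()
    assert g1["HPV16_18"] == pytest.approx(0.6 * g0["HPV16_18"], rel=1e-9)
    # other-HR risk moves only through the (small) released susceptible time
    assert g1["OTHER_HR"] == pytest.approx(g0["OTHER_HR"], rel=0.05)
    full = cohort_solve(
        NOSCREEN_1975, p, demography, VaccinationProfile(1975, coverage=1.0, efficacy_16_18=1.0)
    )
    assert full.lifetime_risk_by_genotype()["HPV16_18"] == 0.0
    zero_eff = cohort_solve(
        NOSCREEN_1975, p, demography, VaccinationProfile(1975, coverage=0.5, efficacy_16_18=0.0)
    )
    assert zero_eff.lifetime_risk == pytest.approx(base.lifetime_risk, rel=1e-12)


@pytest.mark.parametrize("modality", ["CYTOLOGY", "HPV_PRIMARY"])
def test_microsim_agrees_with_solver_single_cell(modality, variants, demography):
    """Spot-check oracle equivalence on one delayed cell per modality
    (the full-grid sweep lives in the acceptance suite)."""
    p = variants["medium_dwell"]
    schedule = build_schedule(ScenarioSpec(1975, 5, modality, 2))
    sol = cohort_solve(schedule, p, demography)
    sample = simulate_cohort(schedule, p, demography, n=60_000, master_seed=2)
    lr, se = lifetime_risk(sample), lifetime_risk_se(sample)
    assert abs(lr - sol.lifetime_risk_percent) <= 3 * se
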