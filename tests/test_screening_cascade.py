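"""Screening cascade: forced pathways, occult behaviour, and agreement of the
stochastic path with the analytic episode probabilities."""

import numpy as np
import pytest

from cervisim.rng import DrawStream, woman_key
from cervisim.screening_cascade import (
    ManagementResult,
    ScreenOutcome,
    followup_visit,
    followup_visit_probs,
    manage_positive,
    perform_screen,
    screen_transition_probs,
    surveillance_visit,
)
from cervisim.states import Genotype, HealthState, StateLabel

from conftest import make_params

HEALTHY = HealthState()
INF16 = HealthState(StateLabel.HPV_INFECTED, Genotype.HPV16_18)
INF_OT = HealthState(StateLabel.HPV_INFECTED, Genotype.OTHER_HR)
PRE16 = HealthState(StateLabel.PRECANCER, Genotype.HPV16_18)
PRE_OT = HealthState(StateLabel.PRECANCER, Genotype.OTHER_HR)
PRE_OCC = HealthState(StateLabel.PRECANCER, Genotype.OTHER_HR, occult=True)
PC16 = HealthState(StateLabel.PRECLINICAL_CANCER, Genotype.HPV16_18)


def stream(i=0):
    return DrawStream(woman_key(123, 7, i))


def test_perfect_specificity_healthy_negative():
    p = make_params(cyto_spec=1.0)
    for i in range(50):
        assert perform_screen(HEALTHY, "CYTOLOGY", p, stream(i)).result == "NEGATIVE"


def test_occult_lesion_never_cytology_positive():
    """Occult lesions are invisible to cytology at any nominal sensitivity."""
    p = make_params(cyto_sens_precancer=1.0, cyto_sens_cancer=1.0)
    occ_pc = HealthState(StateLabel.PRECLINICAL_CANCER, Genotype.OTHER_HR, occult=True)
    for i in range(50):
        assert perform_screen(PRE_OCC, "CYTOLOGY", p, stream(i)).result == "NEGATIVE"
        assert perform_screen(occ_pc, "CYTOLOGY", p, stream(i)).result == "NEGATIVE"


def test_forced_hpv16_18_direct_referral():
    p = make_params(hpv_sens=1.0)
    out = perform_screen(INF16, "HPV_PRIMARY", p, stream())
    assert out.result == "POSITIVE"
    assert out.genotype_call is Genotype.HPV16_18
    assert out.referred_to_colposcopy
    assert out.triage_cytology_result is None


def test_other_hr_triage_gate():
    p = make_params(hpv_sens=1.0, cyto_spec=1.0)
    out = perform_screen(INF_OT, "HPV_PRIMARY", p, stream())
    assert out.result == "POSITIVE" and not out.referred_to_colposcopy
    assert out.triage_cytology_result == "NEGATIVE"


def test_zero_colposcopy_compliance_leaves_state():
    p = make_params(colposcopy_compliance=0.0, hpv_sens=1.0)
    out = perform_screen(PRE16, "HPV_PRIMARY", p, stream())
    result, new = manage_positive(out, PRE16, p, stream())
    assert result == ManagementResult()
    assert new == PRE16


def test_forced_cancer_screen_detection():
    p = make_params(colposcopy_compliance=1.0, colposcopy_sens=1.0, hpv_sens=1.0)
    out = perform_screen(PC16, "HPV_PRIMARY", p, stream())
    result, new = manage_positive(out, PC16, p, stream())
    assert result.cancer_screen_detected
    assert new.label is StateLabel.DIAGNOSED_CANCER


def test_contract_violations():
    p = make_params()
    dead = HealthState(StateLabel.DEAD_OTHER)
    with pytest.raises(ValueError):
        perform_screen(dead, "CYTOLOGY", p, stream())
    not_referred = ScreenOutcome("CYTOLOGY", "NEGATIVE")
    with pytest.raises(ValueError):
        manage_positive(not_referred, PRE16, p, stream())
    with pytest.raises(ValueError):
        ScreenOutcome("CYTOLOGY", "POSITIVE", Genotype.HPV16_18)
    with pytest.raises(ValueError):
        ManagementResult(attended_colposcopy=False, lesion_detected=True)
    with pytest.raises(ValueError):
        surveillance_visit(HEALTHY, p, stream())


@pytest.mark.parametrize("modality", ["CYTOLOGY", "HPV_PRIMARY"])
@pytest.mark.parametrize(
    "state", [HEALTHY, INF16, INF_OT, PRE16, PRE_OT, PRE_OCC, PC16],
    ids=["healthy", "inf16", "infOT", "pre16", "preOT", "preOcc", "pc16"],
)
def test_episode_outcomes_match_analytic_probs(state, modality, medium):
    """Monte Carlo frequencies of full-episode outcomes agree with the
    analytic distribution the cohort solver uses (4 sigma, n = 20,000)."""
    n = 20_000
    counts = {"none": 0, "treated": 0, "surveillance": 0, "diagnosed_screen": 0, "followup": 0}
    for i in range(n):
        draws = stream(i)
        out = perform_screen(state, modality, medium, draws)
        key = "none"
        if out.referred_to_colposcopy:
            result, new = manage_positive(out, state, medium, draws)
            if result.treated:
                key = "treated"
            elif new.surveillance_months_left > 0:
                key = "surveillance"
            elif result.cancer_screen_detected:
                key = "diagnosed_screen"
        resolved = key != "none"
        if modality == "HPV_PRIMARY" and out.result == "POSITIVE" and not resolved:
            key = "followup"
        counts[key] += 1
    expected = screen_transition_probs(state, modality, medium)
    expected["none"] = 1.0 - sum(v for k, v in expected.items() if k != "none")
    for key, p_exp in expected.items():
        se = np.sqrt(max(p_exp * (1 - p_exp), 1e-12) / n)
        assert abs(counts[key] / n - p_exp) <= 4 * se + 1e-9, (key, counts[key] / n, p_exp)


@pytest.mark.parametrize(
    "state", [HEALTHY, INF_OT, PRE16, PRE_OCC, PC16],
    ids=["healthy", "infOT", "pre16", "preOcc", "pc16"],
)
def test_followup_visit_matches_analytic_probs(state, medium):
    """Repeat-HPV visit outcome frequencies agree with the solver's analytic
    distribution (4 sigma, n = 20,000)."""
    n = 20_000
    counts = {"treated": 0, "surveillance": 0, "diagnosed_screen": 0, "rearm": 0, "routine": 0}
    for i in range(n):
        new, detected = followup_visit(state, medium, stream(i))
        if detected:
            counts["diagnosed_screen"] += 1
        elif new.label is StateLabel.HEALTHY and state.label is StateLabel.PRECANCER:
            counts["treated"] += 1
        elif new.surveillance_months_left > 0:
            counts["surveillance"] += 1
        elif new.followup_months_left > 0:
            counts["rearm"] += 1
        else:
            counts["routine"] += 1
    expected = followup_visit_probs(state, medium)
    for key, p_exp in expected.items():
        se = np.sqrt(max(p_exp * (1 - p_exp), 1e-12) / n)
        assert abs(counts[key] / n - p_exp) <= 4 * se + 1e-9, (key, counts[key] / n, p_exp)


def test_specificity_accounting(medium):
    """False-positive colposcopy referrals among lesion-free cytology
    screeners occur at (1 - spec) x reflex-HPV-positive rate."""
    n = 50_000
    referred = 0
    for i in range(n):
        out = perform_screen(HEALTHY, "CYTOLOGY", medium, stream(i))
        referred += out.referred_to_colposcopy
    p_exp = (1 - medium.cyto_spec) * (1 - medium.hpv_spec)
    se = np.sqrt(p_exp * (1 - p_exp) / n)
    assert abs(referred / n - p_exp) <= 4 * se
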