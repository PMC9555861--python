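"""One routine screening episode: primary test, triage, colposcopy referral,
and precancer treatment under imperfect compliance.

Two primary modalities are modeled:

* ``CYTOLOGY`` — Pap smear; positives (ASCUS+) get reflex high-risk HPV
  testing and are referred to colposcopy only if the reflex test is positive.
* ``HPV_PRIMARY`` — high-risk HPV testing with partial genotyping; HPV16/18
  positives are referred directly, other high-risk positives are triaged with
  cytology and referred on ASCUS+.

Referred women attend colposcopy with probability 0.79; detected precancers
are treated with probability 0.73 (Kaiser-style compliance). A detected but
untreated lesion enters annual surveillance, which routine delays never
interrupt. HPV-positive women with negative triage cytology enter a 12-month
repeat-HPV follow-up (colposcopy if still positive); this persistence
follow-up is what gives primary HPV screening its safety margin over
cytology for lesions that cytology cannot grade. Occult lesions are
invisible to cytology (primary or triage) but remain detectable by HPV
testing and colposcopy.

:func:`screen_transition_probs` gives the exact per-state outcome
probabilities of the whole episode; it is the deterministic counterpart used
by the cohort solver and is what the stochastic path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .params import NaturalHistoryParams
from .rng import DrawStream
from .states import Genotype, HealthState, StateLabel

SURVEILLANCE_INTERVAL_MONTHS = 12
FOLLOWUP_INTERVAL_MONTHS = 12


@dataclass(frozen=True)
class ScreenOutcome:
    modality: str
    result: str  # "NEGATIVE" | "POSITIVE"
    genotype_call: Genotype = Genotype.NONE
    referred_to_colposcopy: bool = False
    triage_cytology_result: Optional[str] = None  # "NEGATIVE" | "ASCUS_PLUS"

    def __post_init__(self) -> None:
        if self.genotype_call is not Genotype.NONE and self.modality != "HPV_PRIMARY":
            raise ValueError("genotype call only available for primary HPV testing")
        if self.referred_to_colposcopy and self.result != "POSITIVE":
            raise ValueError("referral requires a positive screen")


@dataclass(frozen=True)
class ManagementResult:
    attended_colposcopy: bool = False
    lesion_detected: bool = False
    treated: bool = False
    cancer_screen_detected: bool = False

    def __post_init__(self) -> None:
        if self.treated and not self.lesion_detected:
            raise ValueError("treated implies lesion_detected")
        if self.lesion_detected and not self.attended_colposcopy:
            raise ValueError("lesion_detected implies attended_colposcopy")


def _check_eligible(state: HealthState) -> None:
    if state.label in (
        StateLabel.DIAGNOSED_CANCER,
        StateLabel.HYSTERECTOMY,
        StateLabel.DEAD_OTHER,
    ):
        raise ValueError(f"state {state.label.value} is not screen-eligible")


def cytology_positive_prob(state: HealthState, params: NaturalHistoryParams) -> float:
    """ASCUS+ probability by health state; occult lesions are never seen."""
    if state.label is StateLabel.PRECANCER:
        return 0.0 if state.occult else params.cyto_sens_precancer
    if state.label is StateLabel.PRECLINICAL_CANCER:
        return 0.0 if state.occult else params.cyto_sens_cancer
    return 1.0 - params.cyto_spec


def hpv_positive_prob(state: HealthState, params: NaturalHistoryParams) -> float:
    if state.label is StateLabel.HEALTHY:
        return 1.0 - params.hpv_spec
    return params.hpv_sens


def perform_screen(
    state: HealthState,
    modality: str,
    params: NaturalHistoryParams,
    draws: DrawStream,
) -> ScreenOutcome:
    """Run one primary screen (test + triage), returning the referral decision.

    Draw order is part of the reproducibility contract: primary test, then
    (cytology) reflex HPV, or (HPV) false-positive genotype split and triage
    cytology — each draw taken only when the preceding result requires it.
    """
    _check_eligible(state)
    if modality == "CYTOLOGY":
        if draws.next() >= cytology_positive_prob(state, params):
            return ScreenOutcome("CYTOLOGY", "NEGATIVE")
        reflex_positive = draws.next() < hpv_positive_prob(state, params)
        return ScreenOutcome(
            "CYTOLOGY", "POSITIVE", Genotype.NONE, referred_to_colposcopy=reflex_positive
        )
    if modality == "HPV_PRIMARY":
        if draws.next() >= hpv_positive_prob(state, params):
            return ScreenOutcome("HPV_PRIMARY", "NEGATIVE")
        if state.label is StateLabel.HEALTHY:
            call = (
                Genotype.HPV16_18
                if draws.next() < params.hpv_false_pos_16_18_fraction
                else Genotype.OTHER_HR
            )
        else:
            call = state.genotype
        if call is Genotype.HPV16_18:
            return ScreenOutcome("HPV_PRIMARY", "POSITIVE", call, referred_to_colposcopy=True)
        triage_pos = draws.next() < cytology_positive_prob(state, params)
        return ScreenOutcome(
            "HPV_PRIMARY",
            "POSITIVE",
            call,
            referred_to_colposcopy=triage_pos,
            triage_cytology_result="ASCUS_PLUS" if triage_pos else "NEGATIVE",
        )
    raise ValueError(f"unknown modality {modality!r}")


def manage_positive(
    outcome: ScreenOutcome,
    state: HealthState,
    params: NaturalHistoryParams,
    draws: DrawStream,
) -> tuple[ManagementResult, HealthState]:
    """Colposcopy attendance, lesion detection, and treatment.

    Returns the management record and the (possibly updated) state. Detected
    untreated precancers enter 12-month surveillance; detected preclinical
    cancers become screen-detected diagnoses. Non-attenders simply return to
    the routine schedule.
    """
    if not outcome.referred_to_colposcopy:
        raise ValueError("manage_positive requires a referred outcome")
    _check_eligible(state)
    if draws.next() >= params.colposcopy_compliance:
        return ManagementResult(), state
    if state.label is StateLabel.PRECANCER:
        if draws.next() < params.colposcopy_sens:
            if draws.next() < params.treatment_compliance:
                return (
                    ManagementResult(True, True, True, False),
                    HealthState(),  # treated: causal infection cleared
                )
            return (
                ManagementResult(True, True, False, False),
                state.with_(
                    surveillance_months_left=SURVEILLANCE_INTERVAL_MONTHS,
                    followup_months_left=0,
                ),
            )
        return ManagementResult(attended_colposcopy=True), state
    if state.label is StateLabel.PRECLINICAL_CANCER:
        if draws.next() < params.colposcopy_sens:
            return (
                ManagementResult(True, True, False, True),
                state.with_(
                    label=StateLabel.DIAGNOSED_CANCER, occult=False,
                    surveillance_months_left=0, followup_months_left=0,
                ),
            )
        return ManagementResult(attended_colposcopy=True), state
    # no lesion present: colposcopy finds nothing
    return ManagementResult(attended_colposcopy=True), state


def surveillance_visit(
    state: HealthState,
    params: NaturalHistoryParams,
    draws: DrawStream,
) -> tuple[HealthState, bool]:
    """Annual re-management of a known, untreated lesion.

    Returns ``(new_state, cancer_detected)``. Attendance is certain
    (surveillance is unaffected by primary-screening disruptions). A still
    present precancer is treated with the treatment-compliance probability; a
    lesion that progressed to preclinical cancer is detected at colposcopy
    with the colposcopy sensitivity.
    """
    if state.label is StateLabel.PRECANCER:
        if draws.next() < params.treatment_compliance:
            return HealthState(), False
        return state.with_(surveillance_months_left=SURVEILLANCE_INTERVAL_MONTHS), False
    if state.label is StateLabel.PRECLINICAL_CANCER:
        if draws.next() < params.colposcopy_sens:
            return (
                state.with_(
                    label=StateLabel.DIAGNOSED_CANCER, occult=False, surveillance_months_left=0
                ),
                True,
            )
        return state.with_(surveillance_months_left=SURVEILLANCE_INTERVAL_MONTHS), False
    raise ValueError("surveillance applies only to lesion states")


def followup_visit(
    state: HealthState,
    params: NaturalHistoryParams,
    draws: DrawStream,
) -> tuple[HealthState, bool]:
    """12-month repeat-HPV visit for a previously HPV-positive, triage-negative
    woman. A persistent positive goes straight to colposcopy (same attendance
    and management as a screen referral); while she keeps testing positive
    without colposcopy-confirmed management she stays on the annual repeat
    track (the clock re-arms); a negative test returns her to routine
    screening. Returns ``(new_state, cancer_detected)``.
    """
    _check_eligible(state)
    state = state.with_(followup_months_left=0)
    rearmed = state.with_(followup_months_left=FOLLOWUP_INTERVAL_MONTHS)
    if draws.next() >= hpv_positive_prob(state, params):
        return state, False
    if draws.next() >= params.colposcopy_compliance:
        return rearmed, False
    if state.label is StateLabel.PRECANCER:
        if draws.next() < params.colposcopy_sens:
            if draws.next() < params.treatment_compliance:
                return HealthState(), False
            return (
                state.with_(surveillance_months_left=SURVEILLANCE_INTERVAL_MONTHS),
                False,
            )
        return rearmed, False
    if state.label is StateLabel.PRECLINICAL_CANCER:
        if draws.next() < params.colposcopy_sens:
            return (
                state.with_(label=StateLabel.DIAGNOSED_CANCER, occult=False),
                True,
            )
        return rearmed, False
    return rearmed, False  # no lesion found: still positive, keep watching


# ---------------------------------------------------------------------------
# Deterministic episode probabilities (used by the cohort solver)
# ---------------------------------------------------------------------------

def referral_prob(state: HealthState, modality: str, params: NaturalHistoryParams) -> float:
    """Probability the whole primary test + triage ends in a colposcopy referral."""
    if modality == "CYTOLOGY":
        return cytology_positive_prob(state, params) * hpv_positive_prob(state, params)
    if modality == "HPV_PRIMARY":
        p_pos = hpv_positive_prob(state, params)
        if state.label is StateLabel.HEALTHY:
            f = params.hpv_false_pos_16_18_fraction
            return p_pos * (f + (1.0 - f) * (1.0 - params.cyto_spec))
        if state.genotype is Genotype.HPV16_18:
            return p_pos
        return p_pos * cytology_positive_prob(state, params)
    raise ValueError(f"unknown modality {modality!r}")


def followup_entry_prob(state: HealthState, modality: str, params: NaturalHistoryParams) -> float:
    """Probability a primary-HPV episode ends with a positive test that is not
    resolved by colposcopy management (triage-negative, colposcopy declined,
    nothing found, or a lesion missed) — i.e. entry to the annual repeat-HPV
    track. Zero for primary cytology."""
    if modality != "HPV_PRIMARY":
        return 0.0
    p_pos = hpv_positive_prob(state, params)
    m = _management_probs(state, referral_prob(state, modality, params), params)
    return p_pos - (m["treated"] + m["surveillance"] + m["diagnosed_screen"])


def _management_probs(state: HealthState, p_ref: float, params: NaturalHistoryParams) -> dict[str, float]:
    p_colpo = p_ref * params.colposcopy_compliance
    out = {"none": 1.0, "treated": 0.0, "surveillance": 0.0, "diagnosed_screen": 0.0}
    if state.label is StateLabel.PRECANCER:
        p_det = p_colpo * params.colposcopy_sens
        out["treated"] = p_det * params.treatment_compliance
        out["surveillance"] = p_det * (1.0 - params.treatment_compliance)
    elif state.label is StateLabel.PRECLINICAL_CANCER:
        out["diagnosed_screen"] = p_colpo * params.colposcopy_sens
    out["none"] = 1.0 - out["treated"] - out["surveillance"] - out["diagnosed_screen"]
    return out


def screen_transition_probs(
    state: HealthState, modality: str, params: NaturalHistoryParams
) -> dict[str, float]:
    """Outcome distribution of one full screening episode for a given state.

    Keys: ``none`` (back to routine, state unchanged), ``treated`` (precancer
    removed, back to HEALTHY), ``surveillance`` (lesion detected, untreated),
    ``diagnosed_screen`` (preclinical cancer screen-detected), ``followup``
    (repeat-HPV clock armed; primary HPV episodes only).
    """
    _check_eligible(state)
    out = _management_probs(state, referral_prob(state, modality, params), params)
    out["followup"] = followup_entry_prob(state, modality, params)
    out["none"] -= out["followup"]
    return out


def followup_visit_probs(state: HealthState, params: NaturalHistoryParams) -> dict[str, float]:
    """Outcome distribution of one repeat-HPV follow-up visit (cf.
    :func:`followup_visit`). Keys: ``routine`` (test negative, back to the
    routine track), ``rearm`` (still positive, repeat again in 12 months),
    plus the management outcomes ``treated`` / ``surveillance`` /
    ``diagnosed_screen``."""
    _check_eligible(state)
    p_pos = hpv_positive_prob(state, params)
    out = _management_probs(state, p_pos, params)
    managed = out.pop("none")  # mass not resolved by colposcopy management
    out["routine"] = 1.0 - p_pos
    out["rearm"] = managed - out["routine"]
    return out


def surveillance_visit_probs(
    label: StateLabel, params: NaturalHistoryParams
) -> dict[str, float]:
    """Outcome distribution of one surveillance visit (cf. :func:`surveillance_visit`)."""
    if label is StateLabel.PRECANCER:
        t = params.treatment_compliance
        return {"treated": t, "reset": 1.0 - t, "diagnosed_screen": 0.0}
    if label is StateLabel.PRECLINICAL_CANCER:
        s = params.colposcopy_sens
        return {"treated": 0.0, "reset": 1.0 - s, "diagnosed_screen": s}
    raise ValueError("surveillance applies only to lesion states")
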