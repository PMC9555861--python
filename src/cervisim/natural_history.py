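"""Monte Carlo natural-history engine: one-cycle updates and full life courses.

The disease process is a discrete-time multistate model over monthly cycles:

    HEALTHY <-> HPV_INFECTED(16/18 | other-HR) <-> PRECANCER -> PRECLINICAL
    -> DIAGNOSED (screen-detected or symptomatic)

with other-cause death and benign hysterectomy as competing events in every
cycle, resolved in a fixed priority order (death, hysterectomy, disease
transition). Sojourns are geometric; the three shipped variants differ only
in rate values, which realizes the short/medium/long dwell-time mechanism
that governs how forgiving a screening delay is.

This module holds the readable per-woman reference implementation
(:func:`step`, :func:`simulate_life_course`). The vectorized engine in
:mod:`cervisim.kernel` implements the identical process (bit-for-bit, same
random-number discipline) for large cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .params import Demography, NaturalHistoryParams, N_MONTHS, VaccinationProfile, UNVACCINATED
from .rng import DrawStream, u01, woman_key
from .scenarios import Schedule
from .screening_cascade import (
    FOLLOWUP_INTERVAL_MONTHS,
    followup_visit,
    manage_positive,
    perform_screen,
    surveillance_visit,
)
from .states import DetectionMode, Genotype, HealthState, StateLabel


class WomanRNG:
    """All random streams for one woman (see :mod:`cervisim.rng`)."""

    __slots__ = ("key", "cascade")

    def __init__(self, key: int):
        self.key = key
        self.cascade = DrawStream(key)

    @classmethod
    def from_seed(cls, master_seed: int, family_id: int = 0, woman_index: int = 0) -> "WomanRNG":
        return cls(woman_key(master_seed, family_id, woman_index))

    def disease_u(self, month: int) -> float:
        return u01(self.key, 0, month)

    def occult_u(self, month: int) -> float:
        return u01(self.key, 1, month)

    def vaccination_u(self) -> float:
        return u01(self.key, 3, 0)


@dataclass(frozen=True)
class DiagnosisRecord:
    age_months: int
    mode: DetectionMode
    genotype: Genotype


@dataclass(frozen=True)
class EndRecord:
    age_months: int
    reason: str  # "REACHED_84" | "DEAD_OTHER"


@dataclass
class Trajectory:
    """One woman's dated state path with screening and diagnosis events."""

    birth_year: int
    state_path: list[tuple[int, HealthState]] = field(default_factory=list)
    screen_log: list[dict] = field(default_factory=list)
    diagnosis: Optional[DiagnosisRecord] = None
    end: Optional[EndRecord] = None

    def to_frame(self) -> pd.DataFrame:
        """Tidy event log: one row per state change."""
        rows = [
            {
                "age_months": m,
                "label": s.label.value,
                "genotype": s.genotype.value,
                "occult": s.occult,
                "surveillance_months_left": s.surveillance_months_left,
            }
            for m, s in self.state_path
        ]
        return pd.DataFrame(rows)

    def validate(self) -> None:
        allowed = {
            StateLabel.HEALTHY: {StateLabel.HPV_INFECTED},
            StateLabel.HPV_INFECTED: {StateLabel.HEALTHY, StateLabel.PRECANCER},
            StateLabel.PRECANCER: {
                StateLabel.HPV_INFECTED,
                StateLabel.PRECLINICAL_CANCER,
                StateLabel.HEALTHY,  # treatment edge
            },
            StateLabel.PRECLINICAL_CANCER: {StateLabel.DIAGNOSED_CANCER},
        }
        absorbing_dest = {StateLabel.HYSTERECTOMY, StateLabel.DEAD_OTHER}
        for (m0, s0), (m1, s1) in zip(self.state_path, self.state_path[1:]):
            if m1 < m0:
                raise ValueError("state path not time-ordered")
            if s1.label == s0.label:
                continue
            if s1.label in absorbing_dest:
                if s0.is_absorbing and s0.label is not StateLabel.HYSTERECTOMY:
                    raise ValueError(f"transition out of absorbing state {s0.label}")
                if s0.label is StateLabel.HYSTERECTOMY and s1.label is not StateLabel.DEAD_OTHER:
                    raise ValueError("hysterectomy permits only other-cause death")
                continue
            if s0.label in absorbing_dest or s0.label is StateLabel.DIAGNOSED_CANCER:
                raise ValueError(f"transition out of absorbing state {s0.label}")
            if s1.label not in allowed.get(s0.label, set()):
                raise ValueError(f"disallowed edge {s0.label.value} -> {s1.label.value}")
        n_diag = sum(1 for _, s in self.state_path if s.label is StateLabel.DIAGNOSED_CANCER)
        if (self.diagnosis is not None) != (n_diag > 0):
            raise ValueError("diagnosis record must be present iff DIAGNOSED_CANCER is reached")


def _resolve_deterministic(
    state: HealthState,
    month: int,
    params: NaturalHistoryParams,
    rng: WomanRNG,
    suppress_symptomatic: bool,
) -> tuple[HealthState, Optional[DetectionMode]]:
    """Deterministic-passage convention: a per-cycle probability of exactly
    1.0 means zero sojourn, so the chain is transited within the cycle."""
    mode: Optional[DetectionMode] = None
    while True:
        if state.label is StateLabel.HPV_INFECTED:
            prog = (
                params.progression_to_precancer_16_18
                if state.genotype is Genotype.HPV16_18
                else params.progression_to_precancer_other
            )
            if prog == 1.0:
                occ = rng.occult_u(month) < params.occult_fraction
                state = state.with_(label=StateLabel.PRECANCER, occult=occ)
                continue
        elif state.label is StateLabel.PRECANCER:
            if params.progression_to_cancer == 1.0:
                state = state.with_(label=StateLabel.PRECLINICAL_CANCER)
                continue
        elif state.label is StateLabel.PRECLINICAL_CANCER:
            if params.symptomatic_detection_rate == 1.0 and not suppress_symptomatic:
                state = state.with_(
                    label=StateLabel.DIAGNOSED_CANCER, occult=False,
                    surveillance_months_left=0, followup_months_left=0,
                )
                mode = DetectionMode.SYMPTOMATIC
                continue
        return state, mode


def step(
    state: HealthState,
    age_months: int,
    params: NaturalHistoryParams,
    demography: Demography,
    rng: WomanRNG,
    vaccinated: bool = False,
    suppress_symptomatic: bool = False,
) -> tuple[HealthState, Optional[DetectionMode]]:
    """One-cycle competing-event update (disease phase only).

    Events are resolved against a single uniform draw partitioned in fixed
    order: other-cause death, hysterectomy, then the state's disease events.
    Returns the next-cycle state and, if the woman was diagnosed this cycle,
    the detection mode (always SYMPTOMATIC here; screen detection belongs to
    the screening cascade). The life course resolves this disease phase
    before any same-cycle screening, so a woman presenting symptomatically
    skips that cycle's screen; ``suppress_symptomatic`` switches the
    symptomatic channel off for one cycle (counterfactual experiments).
    """
    if state.is_absorbing:
        raise ValueError(f"step() called on absorbing state {state.label.value}")
    if not 0 <= age_months < N_MONTHS:
        raise ValueError("age outside the simulated life course")
    u = rng.disease_u(age_months)
    year = age_months // 12
    t = demography.life_table[year]
    if u < t:
        return state.with_(
            label=StateLabel.DEAD_OTHER, genotype=Genotype.NONE, occult=False,
            surveillance_months_left=0, followup_months_left=0,
        ), None
    t += demography.hysterectomy_table[year]
    if u < t:
        return state.with_(
            label=StateLabel.HYSTERECTOMY, genotype=Genotype.NONE, occult=False,
            surveillance_months_left=0, followup_months_left=0,
        ), None

    if state.label is StateLabel.HEALTHY:
        mult = (1.0 - params.vaccine_efficacy_16_18) if vaccinated else 1.0
        a16 = params.hpv_incidence_16_18[year] * mult
        if u < t + a16:
            new = state.with_(label=StateLabel.HPV_INFECTED, genotype=Genotype.HPV16_18)
            return _resolve_deterministic(new, age_months, params, rng, suppress_symptomatic)
        t += a16
        if u < t + params.hpv_incidence_other[year]:
            new = state.with_(label=StateLabel.HPV_INFECTED, genotype=Genotype.OTHER_HR)
            return _resolve_deterministic(new, age_months, params, rng, suppress_symptomatic)
        return state, None

    if state.label is StateLabel.HPV_INFECTED:
        g16 = state.genotype is Genotype.HPV16_18
        clear = params.clearance_16_18 if g16 else params.clearance_other
        prog = params.progression_to_precancer_16_18 if g16 else params.progression_to_precancer_other
        if u < t + clear:
            return state.with_(label=StateLabel.HEALTHY, genotype=Genotype.NONE), None
        if u < t + clear + prog:
            occ = rng.occult_u(age_months) < params.occult_fraction
            new = state.with_(label=StateLabel.PRECANCER, occult=occ)
            return _resolve_deterministic(new, age_months, params, rng, suppress_symptomatic)
        return state, None

    if state.label is StateLabel.PRECANCER:
        g16 = state.genotype is Genotype.HPV16_18
        regr = params.regression_from_precancer_16_18 if g16 else params.regression_from_precancer_other
        if u < t + regr:
            return state.with_(
                label=StateLabel.HPV_INFECTED, occult=False, surveillance_months_left=0
            ), None
        if u < t + regr + params.progression_to_cancer:
            new = state.with_(label=StateLabel.PRECLINICAL_CANCER)
            return _resolve_deterministic(new, age_months, params, rng, suppress_symptomatic)
        return state, None

    if state.label is StateLabel.PRECLINICAL_CANCER:
        s = 0.0 if suppress_symptomatic else params.symptomatic_detection_rate
        if u < t + s:
            return state.with_(
                label=StateLabel.DIAGNOSED_CANCER, occult=False,
                surveillance_months_left=0, followup_months_left=0,
            ), DetectionMode.SYMPTOMATIC
        return state, None

    raise AssertionError("unreachable")


def simulate_life_course(
    schedule: Schedule,
    params: NaturalHistoryParams,
    demography: Demography,
    vaccination: VaccinationProfile = UNVACCINATED,
    rng: WomanRNG | int = 0,
) -> Trajectory:
    """Simulate one woman birth -> age 84 under a routine-screening schedule.

    ``rng`` may be a :class:`WomanRNG` or a bare integer key. The trajectory
    is a pure function of (schedule, parameters, demography, vaccination,
    key): identical inputs give identical trajectories.
    """
    if isinstance(rng, int):
        rng = WomanRNG(rng)
    for m in schedule.event_months():
        if not 0 <= m < N_MONTHS:
            raise ValueError("schedule event outside the simulated life course")
    params = params.replace(vaccine_efficacy_16_18=vaccination.efficacy_16_18)
    vaccinated = rng.vaccination_u() < vaccination.coverage
    screen_at = {e.age_years * 12: e.modality for e in schedule.events}

    state = HealthState()
    traj = Trajectory(birth_year=schedule.spec.birth_year, state_path=[(0, state)])

    def move(month: int, new: HealthState) -> None:
        nonlocal state
        if new != state:
            traj.state_path.append((month, new))
        state = new

    for m in range(N_MONTHS):
        if state.label in (StateLabel.DIAGNOSED_CANCER, StateLabel.DEAD_OTHER):
            break
        if state.label is StateLabel.HYSTERECTOMY:
            if rng.disease_u(m) < demography.life_table[m // 12]:
                move(m, state.with_(label=StateLabel.DEAD_OTHER))
            continue
        # --- phase A: natural-history cycle --------------------------------
        new, mode = step(state, m, params, demography, rng, vaccinated)
        if mode is DetectionMode.SYMPTOMATIC:
            traj.diagnosis = DiagnosisRecord(
                m, mode, state.genotype if state.genotype is not Genotype.NONE else new.genotype
            )
        move(m, new)
        if state.label in (
            StateLabel.DIAGNOSED_CANCER, StateLabel.DEAD_OTHER, StateLabel.HYSTERECTOMY,
        ):
            continue
        # --- phase B: surveillance visit, follow-up visit, or screen -------
        if state.surveillance_months_left > 0:
            left = state.surveillance_months_left - 1
            if left == 0:
                new, detected = surveillance_visit(
                    state.with_(surveillance_months_left=0), params, rng.cascade
                )
                if detected:
                    traj.diagnosis = DiagnosisRecord(m, DetectionMode.SCREEN_DETECTED, state.genotype)
                traj.screen_log.append(
                    {"age_months": m, "event": "SURVEILLANCE", "cancer_detected": detected}
                )
                move(m, new)
            else:
                state = state.with_(surveillance_months_left=left)
        elif state.followup_months_left > 0:
            left = state.followup_months_left - 1
            if left == 0:
                new, detected = followup_visit(
                    state.with_(followup_months_left=0), params, rng.cascade
                )
                if detected:
                    traj.diagnosis = DiagnosisRecord(m, DetectionMode.SCREEN_DETECTED, state.genotype)
                traj.screen_log.append(
                    {"age_months": m, "event": "FOLLOWUP_HPV", "cancer_detected": detected}
                )
                move(m, new)
            else:
                state = state.with_(followup_months_left=left)
        elif m in screen_at and state.screen_eligible:
            modality = screen_at[m]
            outcome = perform_screen(state, modality, params, rng.cascade)
            entry = {
                "age_months": m,
                "event": "SCREEN",
                "modality": modality,
                "result": outcome.result,
                "referred": outcome.referred_to_colposcopy,
            }
            resolved = False
            if outcome.referred_to_colposcopy:
                result, new = manage_positive(outcome, state, params, rng.cascade)
                entry.update(
                    attended=result.attended_colposcopy,
                    lesion_detected=result.lesion_detected,
                    treated=result.treated,
                    cancer_detected=result.cancer_screen_detected,
                )
                resolved = (
                    result.treated
                    or result.cancer_screen_detected
                    or new.surveillance_months_left > 0
                )
                if result.cancer_screen_detected:
                    traj.diagnosis = DiagnosisRecord(m, DetectionMode.SCREEN_DETECTED, state.genotype)
                move(m, new)
            # any unresolved HPV-positive stays under annual repeat testing
            if modality == "HPV_PRIMARY" and outcome.result == "POSITIVE" and not resolved:
                state = state.with_(followup_months_left=FOLLOWUP_INTERVAL_MONTHS)
                entry["followup_armed"] = True
            traj.screen_log.append(entry)

    if state.label is StateLabel.DEAD_OTHER:
        traj.end = EndRecord(traj.state_path[-1][0], "DEAD_OTHER")
    else:
        traj.end = EndRecord(N_MONTHS, "REACHED_84")
    return traj


def dwell_time_summary(params: NaturalHistoryParams) -> dict:
    """Analytic mean sojourn times implied by the geometric rates.

    For a state with total monthly exit probability ``r`` the sojourn is
    geometric with mean ``1/r`` months; because the clock is memoryless this
    is also the mean conditional on which exit occurs, so the total dwell
    from HPV acquisition to symptomatic presentation (conditional on full
    progression, ignoring competing mortality) is the sum of the three stage
    means. Zero rates give infinite sojourns.
    """

    def mean(r: float) -> float:
        return 1.0 / r if r > 0 else float("inf")

    out: dict = {}
    for g, tag in ((Genotype.HPV16_18, "16_18"), (Genotype.OTHER_HR, "other")):
        s1 = mean(
            getattr(params, f"clearance_{tag}") + getattr(params, f"progression_to_precancer_{tag}")
        )
        s2 = mean(getattr(params, f"regression_from_precancer_{tag}") + params.progression_to_cancer)
        s3 = mean(params.symptomatic_detection_rate)
        out[tag] = {
            "hpv_to_precancer_months": s1,
            "precancer_to_preclinical_months": s2,
            "preclinical_to_symptomatic_months": s3,
            "total_months": s1 + s2 + s3,
            "total_years": (s1 + s2 + s3) / 12.0,
        }
    out["total_years"] = 0.5 * (out["16_18"]["total_years"] + out["other"]["total_years"])
    return out
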