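"""Deterministic cohort solver: expected state occupancy and cancer incidence.

Propagates the full probability distribution over the discrete state space
through the same monthly cycle structure as the microsimulation (same event
order, same screening-cascade probabilities, same surveillance and
repeat-HPV follow-up clocks), so it serves as an exact verification oracle:
any microsimulation estimate must agree with it to Monte Carlo error.

State space (242 states):

* HEALTHY and HPV_INFECTED x genotype each carry a follow-up clock
  (0 = routine track, k = months until the repeat-HPV visit);
* PRECANCER and PRECLINICAL_CANCER x genotype x occult-flag carry one clock
  slot ``c``: 0 = routine, 1..12 = surveillance (months to the annual
  re-management visit), 13..24 = follow-up (13 + months-to-visit - 1);
* DIAGNOSED, HYSTERECTOMY, DEAD_OTHER are absorbing (hysterectomized women
  are not followed further; their later other-cause deaths are immaterial to
  every reported outcome).

Diagnosis inflows are recorded per month by detection mode and genotype
rather than split into separate absorbing states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import Demography, NaturalHistoryParams, N_MONTHS, VaccinationProfile, UNVACCINATED
from .scenarios import Schedule
from .screening_cascade import followup_visit_probs, screen_transition_probs
from .states import Genotype, HealthState, StateLabel

N_STATES = 242
H0 = 0                      # HEALTHY, routine track
DIAG_I, HYST_I, DEAD_I = 239, 240, 241
_GENOTYPES = (Genotype.HPV16_18, Genotype.OTHER_HR)


def h_idx(c: int) -> int:
    return c


def inf_idx(g: int, c: int) -> int:
    return 13 + g * 13 + c


def pre_idx(g: int, o: int, c: int) -> int:
    return 39 + (g * 2 + o) * 25 + c


def pc_idx(g: int, o: int, c: int) -> int:
    return 139 + (g * 2 + o) * 25 + c


def _lesion_clock_after(c_upstream: int) -> int:
    """Map a HEALTHY/INFECTED follow-up clock onto the lesion clock slot."""
    return 0 if c_upstream == 0 else 12 + c_upstream


@dataclass
class CohortSolution:
    """Expected outcomes per initial woman (cohort proportions)."""

    birth_year: int
    sympt_inc: np.ndarray    # (N_MONTHS, 2) symptomatic diagnoses by genotype
    screen_inc: np.ndarray   # (N_MONTHS, 2) screen-detected diagnoses by genotype
    eligible_frac: np.ndarray  # (N_MONTHS,) alive, cancer-free, cervix intact at month start
    dead_frac: np.ndarray      # (N_MONTHS + 1,) cumulative other-cause deaths at month start
    occupancy_final: np.ndarray = field(repr=False, default=None)

    @property
    def lifetime_risk(self) -> float:
        """Proportion ever diagnosed with cervical cancer by age 84."""
        return float(self.sympt_inc.sum() + self.screen_inc.sum())

    @property
    def lifetime_risk_percent(self) -> float:
        return 100.0 * self.lifetime_risk

    def lifetime_risk_by_genotype(self) -> dict[str, float]:
        by_g = self.sympt_inc.sum(axis=0) + self.screen_inc.sum(axis=0)
        return {"HPV16_18": float(by_g[0]), "OTHER_HR": float(by_g[1])}

    def survival(self) -> np.ndarray:
        """P(not dead of other causes) at each month start (diagnosed and
        hysterectomized women are not followed for death; exact when disease
        and hysterectomy hazards are zero)."""
        return 1.0 - self.dead_frac

    def window_symptomatic_rate(self, window_months: tuple[int, int]) -> float:
        """Expected symptomatic diagnoses in [start, end) per 100,000 women
        eligible (alive, cancer-free, non-hysterectomized) at window start."""
        ms, me = window_months
        if me <= ms:
            return float("nan")
        num = float(self.sympt_inc[ms:me].sum())
        den = float(self.eligible_frac[ms])
        if den == 0.0:
            return float("nan")
        return num / den * 1e5

    @classmethod
    def mix(cls, sols: list["CohortSolution"], weights: list[float]) -> "CohortSolution":
        w = np.asarray(weights, dtype=float)
        return cls(
            birth_year=sols[0].birth_year,
            sympt_inc=sum(wi * s.sympt_inc for wi, s in zip(w, sols)),
            screen_inc=sum(wi * s.screen_inc for wi, s in zip(w, sols)),
            eligible_frac=sum(wi * s.eligible_frac for wi, s in zip(w, sols)),
            dead_frac=sum(wi * s.dead_frac for wi, s in zip(w, sols)),
            occupancy_final=sum(wi * s.occupancy_final for wi, s in zip(w, sols)),
        )


def _screen_probs(params: NaturalHistoryParams, modality: str):
    """Episode outcome probabilities: lesion states (treated, surveillance,
    diagnosed, follow-up, none) and lesion-free states (follow-up entry)."""
    pre = np.empty((2, 2, 4))  # (treated, surveillance, followup, none)
    pc = np.empty((2, 2, 2))   # (diagnosed, followup)
    free = np.empty(3)         # follow-up entry for HEALTHY, INF16, INFother
    for g, geno in enumerate(_GENOTYPES):
        for o in (0, 1):
            p = screen_transition_probs(
                HealthState(StateLabel.PRECANCER, geno, bool(o)), modality, params
            )
            pre[g, o] = (p["treated"], p["surveillance"], p["followup"], p["none"])
            p = screen_transition_probs(
                HealthState(StateLabel.PRECLINICAL_CANCER, geno, bool(o)), modality, params
            )
            pc[g, o] = (p["diagnosed_screen"], p["followup"])
    free[0] = screen_transition_probs(HealthState(), modality, params)["followup"]
    for g, geno in enumerate(_GENOTYPES):
        free[1 + g] = screen_transition_probs(
            HealthState(StateLabel.HPV_INFECTED, geno), modality, params
        )["followup"]
    return pre, pc, free


def _followup_probs(params: NaturalHistoryParams):
    """Repeat-HPV visit outcomes: lesion states and lesion-free re-arm probs."""
    pre = np.empty((2, 2, 4))  # (treated, surveillance, rearm, routine)
    pc = np.empty((2, 2, 3))   # (diagnosed, rearm, routine)
    for g, geno in enumerate(_GENOTYPES):
        for o in (0, 1):
            p = followup_visit_probs(HealthState(StateLabel.PRECANCER, geno, bool(o)), params)
            pre[g, o] = (p["treated"], p["surveillance"], p["rearm"], p["routine"])
            p = followup_visit_probs(
                HealthState(StateLabel.PRECLINICAL_CANCER, geno, bool(o)), params
            )
            pc[g, o] = (p["diagnosed_screen"], p["rearm"], p["routine"])
    # lesion-free states: the visit never changes health, only the clock
    h_rearm = 1.0 - params.hpv_spec
    inf_rearm = params.hpv_sens
    return pre, pc, h_rearm, inf_rearm


def _resolve_entry(
    occ_vec: np.ndarray,
    mass: float,
    g: int,
    o: int,
    c: int,
    label: StateLabel,
    params: NaturalHistoryParams,
    sympt_flow: np.ndarray,
) -> None:
    """Route mass entering a disease state, applying the deterministic-passage
    convention (per-cycle probability exactly 1.0 = zero sojourn)."""
    if mass == 0.0:
        return
    if label is StateLabel.HPV_INFECTED:
        prog = (
            params.progression_to_precancer_16_18 if g == 0 else params.progression_to_precancer_other
        )
        if prog == 1.0:
            f = params.occult_fraction
            cl = _lesion_clock_after(c)
            _resolve_entry(occ_vec, mass * (1 - f), g, 0, cl, StateLabel.PRECANCER, params, sympt_flow)
            if f > 0:
                _resolve_entry(occ_vec, mass * f, g, 1, cl, StateLabel.PRECANCER, params, sympt_flow)
            return
        occ_vec[inf_idx(g, c)] += mass
        return
    if label is StateLabel.PRECANCER:
        if params.progression_to_cancer == 1.0:
            _resolve_entry(occ_vec, mass, g, o, c, StateLabel.PRECLINICAL_CANCER, params, sympt_flow)
            return
        occ_vec[pre_idx(g, o, c)] += mass
        return
    if label is StateLabel.PRECLINICAL_CANCER:
        if params.symptomatic_detection_rate == 1.0:
            sympt_flow[g] += mass
            occ_vec[DIAG_I] += mass
            return
        occ_vec[pc_idx(g, o, c)] += mass
        return
    raise AssertionError("unreachable")


def cohort_solve(
    schedule: Schedule,
    params: NaturalHistoryParams,
    demography: Demography,
    vaccination: VaccinationProfile = UNVACCINATED,
) -> CohortSolution:
    """Forward-propagate the state distribution birth -> age 84.

    Vaccinated and unvaccinated strata are solved separately and mixed by
    coverage (the dynamics are linear in the initial mass)."""
    if vaccination.coverage == 0.0:
        return _solve_stratum(schedule, params, demography, 1.0)
    mult = 1.0 - vaccination.efficacy_16_18
    unvac = _solve_stratum(schedule, params, demography, 1.0)
    vac = _solve_stratum(schedule, params, demography, mult)
    return CohortSolution.mix([unvac, vac], [1.0 - vaccination.coverage, vaccination.coverage])


def _solve_stratum(
    schedule: Schedule,
    params: NaturalHistoryParams,
    demography: Demography,
    inc16_mult: float,
) -> CohortSolution:
    death_m, hyst_m = demography.monthly()
    idx = np.arange(N_MONTHS) // 12
    inc16_m = params.hpv_incidence_16_18[idx] * inc16_mult
    incot_m = params.hpv_incidence_other[idx]

    clear = (params.clearance_16_18, params.clearance_other)
    prog_pre = (params.progression_to_precancer_16_18, params.progression_to_precancer_other)
    regr = (params.regression_from_precancer_16_18, params.regression_from_precancer_other)
    progca = params.progression_to_cancer
    sympt = params.symptomatic_detection_rate
    occfrac = params.occult_fraction
    tc = params.treatment_compliance
    cs = params.colposcopy_sens

    # per-cycle stochasticity validation (worst month)
    worst = float(np.max(death_m + hyst_m))
    if np.max(death_m + hyst_m + inc16_m + incot_m) > 1.0 + 1e-12:
        raise ValueError("healthy-state cycle probabilities sum above 1")
    for g in (0, 1):
        if worst + clear[g] + prog_pre[g] > 1.0 + 1e-12:
            raise ValueError("infected-state cycle probabilities sum above 1")
        if worst + regr[g] + progca > 1.0 + 1e-12:
            raise ValueError("precancer-state cycle probabilities sum above 1")
    if worst + sympt > 1.0 + 1e-12:
        raise ValueError("preclinical-state cycle probabilities sum above 1")

    screen_ops: dict[int, tuple] = {}
    for e in schedule.events:
        screen_ops[e.age_years * 12] = _screen_probs(params, e.modality)
    fup_pre, fup_pc, fup_h_rearm, fup_inf_rearm = _followup_probs(params)

    occ = np.zeros(N_STATES)
    occ[H0] = 1.0
    sympt_inc = np.zeros((N_MONTHS, 2))
    screen_inc = np.zeros((N_MONTHS, 2))
    eligible = np.zeros(N_MONTHS)
    dead = np.zeros(N_MONTHS + 1)

    combos = [(g, o) for g in (0, 1) for o in (0, 1)]
    h_slice = slice(h_idx(0), h_idx(12) + 1)
    inf_slices = [slice(inf_idx(g, 0), inf_idx(g, 12) + 1) for g in (0, 1)]
    pre_slices = {(g, o): slice(pre_idx(g, o, 0), pre_idx(g, o, 24) + 1) for g, o in combos}
    pc_slices = {(g, o): slice(pc_idx(g, o, 0), pc_idx(g, o, 24) + 1) for g, o in combos}

    for m in range(N_MONTHS):
        eligible[m] = occ[:DIAG_I].sum()
        dead[m] = occ[DEAD_I]
        is_screen = m in screen_ops

        # --- phase A: natural-history cycle --------------------------------
        d, h = death_m[m], hyst_m[m]
        # zero-sojourn chaining is active only for probability-1 rates
        chain = (
            sympt == 1.0 or progca == 1.0 or prog_pre[0] == 1.0 or prog_pre[1] == 1.0
        )
        new = np.zeros(N_STATES)
        new[DIAG_I] = occ[DIAG_I]
        new[HYST_I] = occ[HYST_I]
        alive = occ[:DIAG_I].sum()
        new[DEAD_I] = occ[DEAD_I] + alive * d
        new[HYST_I] += alive * h

        # healthy (clock carried through acquisition)
        a16, aot = inc16_m[m], incot_m[m]
        hblk = occ[h_slice]
        new[h_slice] += hblk * (1.0 - d - h - a16 - aot)
        if chain:
            for c in range(13):
                _resolve_entry(new, hblk[c] * a16, 0, 0, c, StateLabel.HPV_INFECTED, params, sympt_inc[m])
                _resolve_entry(new, hblk[c] * aot, 1, 0, c, StateLabel.HPV_INFECTED, params, sympt_inc[m])
        else:
            new[inf_slices[0]] += hblk * a16
            new[inf_slices[1]] += hblk * aot
        # infected (clock carried; clearance keeps the clock)
        for g in (0, 1):
            blk = occ[inf_slices[g]]
            if blk.sum() > 0.0:
                new[inf_slices[g]] += blk * (1.0 - d - h - clear[g] - prog_pre[g])
                new[h_slice] += blk * clear[g]
                if prog_pre[g] > 0.0:
                    for c in range(13):
                        pmass = blk[c] * prog_pre[g]
                        if pmass == 0.0:
                            continue
                        cl = _lesion_clock_after(c)
                        if chain:
                            _resolve_entry(new, pmass * (1 - occfrac), g, 0, cl, StateLabel.PRECANCER, params, sympt_inc[m])
                            if occfrac > 0.0:
                                _resolve_entry(new, pmass * occfrac, g, 1, cl, StateLabel.PRECANCER, params, sympt_inc[m])
                        else:
                            new[pre_idx(g, 0, cl)] += pmass * (1 - occfrac)
                            new[pre_idx(g, 1, cl)] += pmass * occfrac
        # precancer / preclinical
        for g, o in combos:
            blk = occ[pre_slices[(g, o)]]
            if blk.sum() > 0.0:
                new[pre_slices[(g, o)]] += blk * (1.0 - d - h - regr[g] - progca)
                # regression: surveillance lapses, a follow-up clock persists
                if regr[g] > 0.0:
                    new[inf_idx(g, 0)] += blk[:13].sum() * regr[g]
                    new[inf_idx(g, 1):inf_idx(g, 12) + 1] += blk[13:25] * regr[g]
                if progca > 0.0:
                    if chain:
                        for c in range(25):
                            _resolve_entry(new, blk[c] * progca, g, o, c, StateLabel.PRECLINICAL_CANCER, params, sympt_inc[m])
                    else:
                        new[pc_slices[(g, o)]] += blk * progca
            blk = occ[pc_slices[(g, o)]]
            if blk.sum() > 0.0:
                new[pc_slices[(g, o)]] += blk * (1.0 - d - h - sympt)
                flow = blk.sum() * sympt
                sympt_inc[m, g] += flow
                new[DIAG_I] += flow
        occ = new

        # --- phase B: clocks (decrement; visit when they hit zero) ---------
        # women whose visit returns them to the routine track (including
        # those treated at a visit) are buffered past this month's routine
        # screen: a woman is never screened twice in one cycle
        buf = np.zeros(N_STATES)
        visit = occ[h_idx(1)]
        occ[h_idx(1):h_idx(12)] = occ[h_idx(2):h_idx(12) + 1].copy()
        occ[h_idx(12)] = visit * fup_h_rearm
        buf[h_idx(0)] += visit * (1.0 - fup_h_rearm)
        for g in (0, 1):
            visit = occ[inf_idx(g, 1)]
            occ[inf_idx(g, 1):inf_idx(g, 12)] = occ[inf_idx(g, 2):inf_idx(g, 12) + 1].copy()
            occ[inf_idx(g, 12)] = visit * fup_inf_rearm
            buf[inf_idx(g, 0)] += visit * (1.0 - fup_inf_rearm)
        for g, o in combos:
            blk = occ[pre_slices[(g, o)]].copy()
            if blk[1:].sum() > 0.0:
                new_blk = np.zeros(25)
                new_blk[0] = blk[0]
                new_blk[1:12] = blk[2:13]     # surveillance clock
                new_blk[13:24] = blk[14:25]   # follow-up clock
                surv_visit = blk[1]
                buf[H0] += surv_visit * tc
                new_blk[12] += surv_visit * (1.0 - tc)
                fup_visit = blk[13]
                if fup_visit > 0.0:
                    treated, to_surv, rearm, routine = fup_pre[g, o]
                    buf[H0] += fup_visit * treated
                    new_blk[12] += fup_visit * to_surv
                    new_blk[24] += fup_visit * rearm
                    buf[pre_idx(g, o, 0)] += fup_visit * routine
                occ[pre_slices[(g, o)]] = new_blk
            blk = occ[pc_slices[(g, o)]].copy()
            if blk[1:].sum() > 0.0:
                new_blk = np.zeros(25)
                new_blk[0] = blk[0]
                new_blk[1:12] = blk[2:13]
                new_blk[13:24] = blk[14:25]
                surv_visit = blk[1]
                screen_inc[m, g] += surv_visit * cs
                occ[DIAG_I] += surv_visit * cs
                new_blk[12] += surv_visit * (1.0 - cs)
                fup_visit = blk[13]
                if fup_visit > 0.0:
                    pd, rearm, routine = fup_pc[g, o]
                    screen_inc[m, g] += fup_visit * pd
                    occ[DIAG_I] += fup_visit * pd
                    new_blk[24] += fup_visit * rearm
                    buf[pc_idx(g, o, 0)] += fup_visit * routine
                occ[pc_slices[(g, o)]] = new_blk

        # --- phase C: routine screen on routine-track (clock 0) states -----
        if is_screen:
            pre_p, pc_p, free_p = screen_ops[m]
            mass = occ[h_idx(0)]
            if mass > 0.0 and free_p[0] > 0.0:
                occ[h_idx(0)] = mass * (1.0 - free_p[0])
                occ[h_idx(12)] += mass * free_p[0]
            for g in (0, 1):
                mass = occ[inf_idx(g, 0)]
                if mass > 0.0 and free_p[1 + g] > 0.0:
                    occ[inf_idx(g, 0)] = mass * (1.0 - free_p[1 + g])
                    occ[inf_idx(g, 12)] += mass * free_p[1 + g]
            for g, o in combos:
                i0 = pre_idx(g, o, 0)
                mass = occ[i0]
                if mass > 0.0:
                    treated, surv, fup, none = pre_p[g, o]
                    occ[i0] = mass * none
                    occ[H0] += mass * treated
                    occ[pre_idx(g, o, 12)] += mass * surv
                    occ[pre_idx(g, o, 24)] += mass * fup
                i0 = pc_idx(g, o, 0)
                mass = occ[i0]
                if mass > 0.0:
                    pd, fup = pc_p[g, o]
                    occ[i0] = mass * (1.0 - pd - fup)
                    screen_inc[m, g] += mass * pd
                    occ[DIAG_I] += mass * pd
                    occ[pc_idx(g, o, 24)] += mass * fup
        occ += buf

        total = occ.sum()
        if abs(total - 1.0) > 1e-10:
            raise AssertionError(f"occupancy not conserved at month {m}: {total}")

    dead[N_MONTHS] = occ[DEAD_I]
    return CohortSolution(
        birth_year=schedule.spec.birth_year,
        sympt_inc=sympt_inc,
        screen_inc=screen_inc,
        eligible_frac=eligible,
        dead_frac=dead,
        occupancy_final=occ,
    )
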