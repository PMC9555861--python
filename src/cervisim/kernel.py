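"""Vectorized per-woman life-course engine (numba).

Implements exactly the same monthly process as
:func:`cervisim.natural_history.simulate_life_course` — same event order,
same counter-based random-number discipline — compiled for large cohorts.
Bit-for-bit agreement with the reference driver is enforced by tests.

Outputs are compact per-woman arrays (diagnosis month/mode/genotype, death
and hysterectomy months); summary statistics are computed from them in
:mod:`cervisim.outcomes`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit, uint64

from .params import Demography, NaturalHistoryParams, N_MONTHS, VaccinationProfile, UNVACCINATED
from .rng import string_id
from .scenarios import Schedule

_GOLDEN = uint64(0x9E3779B97F4A7C15)
_C2 = uint64(0xC2B2AE3D27D4EB4F)

# label codes
_H, _INF, _PRE, _PC, _DIAG, _HYST, _DEAD = 0, 1, 2, 3, 4, 5, 6


@njit(cache=True, inline="always")
def _mix64(z):
    z = uint64(z)
    z ^= z >> uint64(30)
    z *= uint64(0xBF58476D1CE4E5B9)
    z ^= z >> uint64(27)
    z *= uint64(0x94D049BB133111EB)
    z ^= z >> uint64(31)
    return z


@njit(cache=True, inline="always")
def _u01(key, stream, ctr):
    z = _mix64(uint64(key) ^ (_GOLDEN * (uint64(stream) + uint64(1))))
    z = _mix64(z ^ (_C2 * (uint64(ctr) + uint64(1))))
    return (z >> uint64(11)) * 1.1102230246251565e-16  # * 2**-53


@njit(cache=True, inline="always")
def _woman_key(master_seed, family_id, woman_index):
    k = _mix64(uint64(master_seed) ^ (_GOLDEN * (uint64(family_id) + uint64(1))))
    return _mix64(k ^ (_GOLDEN * (uint64(woman_index) + uint64(1))))


@njit(cache=True)
def _simulate(
    n, master_seed, family_id,
    death_m, hyst_m, inc16_m, incot_m,
    sc,  # scalar parameter vector, see _pack_scalars
    screen_month, screen_hpv,
    diag_month, diag_mode, diag_geno, death_month, hyst_month,
):
    (clear16, clearot, prog16, progot, regr16, regrot, progca, sympt, occfrac,
     cs_pre, cs_can, cspec, hsens, hspec, fp1618, colpo_sens, colpo_comp,
     treat_comp, vacc_eff, coverage) = (
        sc[0], sc[1], sc[2], sc[3], sc[4], sc[5], sc[6], sc[7], sc[8], sc[9],
        sc[10], sc[11], sc[12], sc[13], sc[14], sc[15], sc[16], sc[17], sc[18], sc[19],
    )
    nscreens = screen_month.shape[0]
    for i in range(n):
        key = _woman_key(master_seed, family_id, uint64(i))
        vaccinated = _u01(key, 3, 0) < coverage
        mult16 = (1.0 - vacc_eff) if vaccinated else 1.0
        label = _H
        g = -1  # 0 = HPV16/18, 1 = other-HR
        occ = False
        surv = 0  # months until annual surveillance visit (detected lesion)
        fk = 0    # months until repeat-HPV follow-up visit
        si = 0
        ctr = 0  # cascade draw counter
        dm = -1
        dmo = -1
        dg = -1
        dth = -1
        hys = -1
        for m in range(N_MONTHS):
            if label == _DIAG or label == _DEAD:
                break
            is_screen = False
            is_hpv_screen = False
            if si < nscreens and screen_month[si] == m:
                is_screen = True
                is_hpv_screen = screen_hpv[si] != 0
                si += 1
            if label == _HYST:
                if _u01(key, 0, m) < death_m[m]:
                    label = _DEAD
                    dth = m
                continue
            # --- phase A: natural-history cycle ----------------------------
            u = _u01(key, 0, m)
            t = death_m[m]
            if u < t:
                label = _DEAD; dth = m
                continue
            t += hyst_m[m]
            if u < t:
                label = _HYST; hys = m
                g = -1; occ = False; surv = 0; fk = 0
                continue
            advanced = False
            if label == _H:
                a16 = inc16_m[m] * mult16
                if u < t + a16:
                    label = _INF; g = 0; advanced = True
                elif u < t + a16 + incot_m[m]:
                    label = _INF; g = 1; advanced = True
            elif label == _INF:
                cl = clear16 if g == 0 else clearot
                pr = prog16 if g == 0 else progot
                if u < t + cl:
                    label = _H; g = -1
                elif u < t + cl + pr:
                    label = _PRE; advanced = True
                    occ = _u01(key, 1, m) < occfrac
            elif label == _PRE:
                rg = regr16 if g == 0 else regrot
                if u < t + rg:
                    label = _INF; occ = False; surv = 0
                elif u < t + rg + progca:
                    label = _PC; advanced = True
            else:  # _PC
                if u < t + sympt:
                    label = _DIAG; dm = m; dmo = 0; dg = g
                    continue
            if advanced:
                # deterministic passage (per-cycle probability exactly 1)
                if label == _INF:
                    pr = prog16 if g == 0 else progot
                    if pr == 1.0:
                        label = _PRE
                        occ = _u01(key, 1, m) < occfrac
                if label == _PRE and progca == 1.0:
                    label = _PC
                if label == _PC and sympt == 1.0:
                    label = _DIAG; dm = m; dmo = 0; dg = g
                    continue
            # --- phase B: surveillance, follow-up, or routine screen -------
            if surv > 0:
                surv -= 1
                if surv == 0:
                    if label == _PRE:
                        u = _u01(key, 2, ctr); ctr += 1
                        if u < treat_comp:
                            label = _H; g = -1; occ = False
                        else:
                            surv = 12
                    else:  # _PC
                        u = _u01(key, 2, ctr); ctr += 1
                        if u < colpo_sens:
                            label = _DIAG; dm = m; dmo = 1; dg = g
                            continue
                        surv = 12
            elif fk > 0:
                fk -= 1
                if fk == 0:
                    # repeat-HPV follow-up visit (annual while still positive)
                    ph = hsens if label >= _INF else 1.0 - hspec
                    u = _u01(key, 2, ctr); ctr += 1
                    if u < ph:
                        fk = 12  # persistent positive: stay on the repeat track
                        u = _u01(key, 2, ctr); ctr += 1
                        if u < colpo_comp:
                            if label == _PRE:
                                u = _u01(key, 2, ctr); ctr += 1
                                if u < colpo_sens:
                                    fk = 0
                                    u = _u01(key, 2, ctr); ctr += 1
                                    if u < treat_comp:
                                        label = _H; g = -1; occ = False
                                    else:
                                        surv = 12
                            elif label == _PC:
                                u = _u01(key, 2, ctr); ctr += 1
                                if u < colpo_sens:
                                    fk = 0
                                    label = _DIAG; dm = m; dmo = 1; dg = g
                                    continue
            elif is_screen and label <= _PC:
                referred = False
                hpv_pos = False
                resolved = False
                if not is_hpv_screen:  # cytology primary
                    if label == _PRE:
                        p_cyto = 0.0 if occ else cs_pre
                    elif label == _PC:
                        p_cyto = 0.0 if occ else cs_can
                    else:
                        p_cyto = 1.0 - cspec
                    u = _u01(key, 2, ctr); ctr += 1
                    if u < p_cyto:
                        ph = hsens if label >= _INF else 1.0 - hspec
                        u = _u01(key, 2, ctr); ctr += 1
                        if u < ph:
                            referred = True
                else:  # HPV primary with partial genotyping
                    ph = hsens if label >= _INF else 1.0 - hspec
                    u = _u01(key, 2, ctr); ctr += 1
                    if u < ph:
                        hpv_pos = True
                        if label == _H:
                            u = _u01(key, 2, ctr); ctr += 1
                            call1618 = u < fp1618
                        else:
                            call1618 = g == 0
                        if call1618:
                            referred = True
                        else:
                            if label == _PRE:
                                p_tri = 0.0 if occ else cs_pre
                            elif label == _PC:
                                p_tri = 0.0 if occ else cs_can
                            else:
                                p_tri = 1.0 - cspec
                            u = _u01(key, 2, ctr); ctr += 1
                            if u < p_tri:
                                referred = True
                if referred:
                    u = _u01(key, 2, ctr); ctr += 1
                    if u < colpo_comp:
                        if label == _PRE:
                            u = _u01(key, 2, ctr); ctr += 1
                            if u < colpo_sens:
                                u = _u01(key, 2, ctr); ctr += 1
                                resolved = True
                                if u < treat_comp:
                                    label = _H; g = -1; occ = False
                                else:
                                    surv = 12
                        elif label == _PC:
                            u = _u01(key, 2, ctr); ctr += 1
                            if u < colpo_sens:
                                label = _DIAG; dm = m; dmo = 1; dg = g
                                continue
                # any unresolved HPV-positive: annual repeat-HPV track
                if hpv_pos and not resolved:
                    fk = 12
        diag_month[i] = dm
        diag_mode[i] = dmo
        diag_geno[i] = dg
        death_month[i] = dth
        hyst_month[i] = hys


@dataclass
class CohortSample:
    """Compact per-woman outcomes for a simulated cohort cell."""

    birth_year: int
    n: int
    diag_month: np.ndarray   # month of diagnosis, -1 if never
    diag_mode: np.ndarray    # 0 symptomatic, 1 screen-detected, -1 none
    diag_geno: np.ndarray    # 0 HPV16/18, 1 other-HR, -1 none
    death_month: np.ndarray  # month of other-cause death, -1 if reached 84
    hyst_month: np.ndarray   # month of hysterectomy, -1 if none


def _pack_scalars(params: NaturalHistoryParams, vaccination: VaccinationProfile) -> np.ndarray:
    return np.array(
        [
            params.clearance_16_18, params.clearance_other,
            params.progression_to_precancer_16_18, params.progression_to_precancer_other,
            params.regression_from_precancer_16_18, params.regression_from_precancer_other,
            params.progression_to_cancer, params.symptomatic_detection_rate,
            params.occult_fraction,
            params.cyto_sens_precancer, params.cyto_sens_cancer, params.cyto_spec,
            params.hpv_sens, params.hpv_spec, params.hpv_false_pos_16_18_fraction,
            params.colposcopy_sens, params.colposcopy_compliance, params.treatment_compliance,
            vaccination.efficacy_16_18, vaccination.coverage,
        ],
        dtype=np.float64,
    )


def simulate_cohort(
    schedule: Schedule,
    params: NaturalHistoryParams,
    demography: Demography,
    vaccination: VaccinationProfile = UNVACCINATED,
    n: int = 10_000,
    master_seed: int = 0,
    family_id: int | None = None,
) -> CohortSample:
    """Simulate ``n`` women through one scenario cell.

    ``family_id`` defaults to a stable hash of the schedule's scenario family
    (cohort x frequency x modality), so delay arms of the same family share
    per-woman random streams (common random numbers).
    """
    if family_id is None:
        family_id = string_id(schedule.spec.family_id)
    death_m, hyst_m = demography.monthly()
    idx = np.arange(N_MONTHS) // 12
    inc16_m = params.hpv_incidence_16_18[idx]
    incot_m = params.hpv_incidence_other[idx]
    months = np.array(schedule.event_months(), dtype=np.int64)
    is_hpv = np.array(
        [1 if e.modality == "HPV_PRIMARY" else 0 for e in schedule.events], dtype=np.uint8
    )
    diag_month = np.empty(n, dtype=np.int32)
    diag_mode = np.empty(n, dtype=np.int8)
    diag_geno = np.empty(n, dtype=np.int8)
    death_month = np.empty(n, dtype=np.int32)
    hyst_month = np.empty(n, dtype=np.int32)
    _simulate(
        n, np.uint64(master_seed & ((1 << 64) - 1)), np.uint64(family_id),
        death_m, hyst_m, inc16_m, incot_m,
        _pack_scalars(params, vaccination),
        months, is_hpv,
        diag_month, diag_mode, diag_geno, death_month, hyst_month,
    )
    return CohortSample(
        birth_year=schedule.spec.birth_year, n=n,
        diag_month=diag_month, diag_mode=diag_mode, diag_geno=diag_geno,
        death_month=death_month, hyst_month=hyst_month,
    )
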