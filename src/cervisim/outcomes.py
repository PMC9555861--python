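"""Outcome statistics: short-term symptomatic-cancer rates and rate ratios
during a delay window; long-term lifetime risk, excess cases per 100,000,
and percent of cancers prevented.

All functions accept either a simulated :class:`~cervisim.kernel.CohortSample`
(or a list of :class:`~cervisim.natural_history.Trajectory`) or a
deterministic :class:`~cervisim.cohort.CohortSolution`; scale conventions
follow the reporting style of the underlying analysis: lifetime risks in
percent, window rates per 100,000 women, excess cases per 100,000.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import CohortSolution
from .kernel import CohortSample
from .natural_history import Trajectory
from .states import DetectionMode

COHORTS = (1965, 1975, 1985)


def _as_sample(obj) -> CohortSample:
    if isinstance(obj, CohortSample):
        return obj
    trajectories = list(obj)
    n = len(trajectories)
    diag_month = np.full(n, -1, dtype=np.int32)
    diag_mode = np.full(n, -1, dtype=np.int8)
    diag_geno = np.full(n, -1, dtype=np.int8)
    death_month = np.full(n, -1, dtype=np.int32)
    hyst_month = np.full(n, -1, dtype=np.int32)
    for i, t in enumerate(trajectories):
        if t.end is None:
            raise ValueError("truncated trajectory: no end record")
        if t.diagnosis is not None:
            diag_month[i] = t.diagnosis.age_months
            diag_mode[i] = 0 if t.diagnosis.mode is DetectionMode.SYMPTOMATIC else 1
            diag_geno[i] = 0 if t.diagnosis.genotype.value == "HPV16_18" else 1
        if t.end.reason == "DEAD_OTHER":
            death_month[i] = t.end.age_months
        for m, s in t.state_path:
            if s.label.value == "HYSTERECTOMY":
                hyst_month[i] = m
                break
    return CohortSample(
        birth_year=trajectories[0].birth_year if trajectories else 0,
        n=n, diag_month=diag_month, diag_mode=diag_mode, diag_geno=diag_geno,
        death_month=death_month, hyst_month=hyst_month,
    )


def lifetime_risk(result: CohortSample | CohortSolution | Iterable[Trajectory]) -> float:
    """Percent of all women (competing deaths included in the denominator)
    ever diagnosed with cervical cancer by age 84."""
    if isinstance(result, CohortSolution):
        return result.lifetime_risk_percent
    sample = _as_sample(result)
    return 100.0 * float(np.mean(sample.diag_month >= 0))


def lifetime_risk_se(result: CohortSample | Iterable[Trajectory]) -> float:
    """Monte Carlo standard error of :func:`lifetime_risk` (percent scale)."""
    sample = _as_sample(result)
    p = float(np.mean(sample.diag_month >= 0))
    return 100.0 * math.sqrt(p * (1.0 - p) / sample.n)


def symptomatic_rate_in_window(
    result: CohortSample | CohortSolution | Iterable[Trajectory],
    window_months: tuple[int, int],
) -> float:
    """Symptomatic diagnoses during the half-open window [start, end), per
    100,000 women alive, cancer-free and hysterectomy-free at window start.
    An empty window (no delay) has no defined rate and returns NaN."""
    ms, me = window_months
    if me <= ms:
        return float("nan")
    if isinstance(result, CohortSolution):
        return result.window_symptomatic_rate(window_months)
    s = _as_sample(result)
    eligible = (
        ((s.death_month < 0) | (s.death_month >= ms))
        & ((s.hyst_month < 0) | (s.hyst_month >= ms))
        & ((s.diag_month < 0) | (s.diag_month >= ms))
    )
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        return float("nan")
    cases = int(
        ((s.diag_mode == 0) & (s.diag_month >= ms) & (s.diag_month < me) & eligible).sum()
    )
    return cases / n_eligible * 1e5


def short_term_rate_ratio(rate_cell: float, rate_comparator: float) -> float:
    """RR of within-window symptomatic cancer versus the guidelines-compliant
    comparator; NaN when the comparator rate is zero (undefined)."""
    if not rate_comparator > 0.0 or math.isnan(rate_cell):
        return float("nan")
    return rate_cell / rate_comparator


def excess_cases_per_100k(lr_delay_percent: float, lr_nodelay_percent: float) -> tuple[float, float]:
    """Absolute lifetime-risk change (percentage points) and the equivalent
    excess cases per 100,000 women."""
    delta = lr_delay_percent - lr_nodelay_percent
    return delta, delta * 1000.0


def percent_prevented(lr_scenario_percent: float, lr_noscreen_percent: float) -> float:
    """Percent of no-screening cancers prevented by a screening scenario."""
    if not lr_noscreen_percent > 0.0:
        return float("nan")
    return (lr_noscreen_percent - lr_scenario_percent) / lr_noscreen_percent * 100.0


def average_over_cohorts(values: Mapping[int, float] | Sequence[float]) -> float:
    """Unweighted mean over the three birth cohorts (all must be present)."""
    if isinstance(values, Mapping):
        missing = [c for c in COHORTS if c not in values]
        if missing:
            raise ValueError(f"missing cohort values: {missing}")
        vals = [values[c] for c in COHORTS]
    else:
        vals = list(values)
        if len(vals) != len(COHORTS):
            raise ValueError(f"expected {len(COHORTS)} cohort values, got {len(vals)}")
    return float(np.mean(vals))


def round_risk_percent(value: float) -> float:
    """Reporting convention: risks rounded to the nearest 0.001%."""
    return float(np.round(value, 3))
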