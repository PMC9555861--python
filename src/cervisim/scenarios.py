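"""Routine-screening schedules under pandemic-style delay scenarios.

A scenario cell fixes a birth cohort, an underlying screening frequency, a
primary test modality, and a delay applied to the screen that was due in the
disruption year (2020). Schedules are anchored *backward* from 2020: the
cohorts are aligned so that 2020 is exactly one inter-screen interval since
the last screen, i.e. a screen was due in 2020. During a delay of ``d`` years
there is a 100% loss of primary screening; the delayed screen happens at
2020 + d and subsequent screens follow at the fixed pre-pandemic frequency
from that shifted anchor. Screens that would fall outside the eligible ages
(21–65) are dropped, never moved — which is what produces the "missed final
screen" effect for infrequent screeners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

Modality = str  # "CYTOLOGY" | "HPV_PRIMARY"

MODALITIES = ("CYTOLOGY", "HPV_PRIMARY")
DEFAULT_COHORTS = (1965, 1975, 1985)
DEFAULT_FREQUENCIES = (1, 3, 5, 10)
DEFAULT_DELAYS = (0, 1, 2, 5)

#: Sentinel returned by :func:`last_routine_screen_age` for empty schedules.
NO_SCREENS = -1


@dataclass(frozen=True)
class PolicyRules:
    """US-style eligibility rules: cytology from 21, optional switch to
    primary HPV testing from age 30, nothing after 65."""

    start_age: int = 21
    stop_age: int = 65
    hpv_switch_age: int = 30
    disruption_start_year: int = 2020

    def __post_init__(self) -> None:
        if not (self.start_age < self.hpv_switch_age < self.stop_age):
            raise ValueError("require start_age < hpv_switch_age < stop_age")


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the experiment grid."""

    birth_year: int
    frequency_years: Optional[int]  # None = no-screening reference cell
    modality: Modality = "CYTOLOGY"
    delay_years: int = 0
    policy: PolicyRules = field(default_factory=PolicyRules)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.frequency_years is not None and self.frequency_years < 1:
            raise ValueError("frequency_years must be >= 1")
        if self.delay_years < 0:
            raise ValueError("delay_years must be >= 0")

    @classmethod
    def no_screening(cls, birth_year: int, policy: PolicyRules | None = None) -> "ScenarioSpec":
        return cls(birth_year, None, "CYTOLOGY", 0, policy or PolicyRules())

    @property
    def is_no_screening(self) -> bool:
        return self.frequency_years is None

    @property
    def cell_id(self) -> str:
        if self.is_no_screening:
            return f"{self.birth_year}-noscreen"
        return f"{self.birth_year}-{self.frequency_years}y-{self.modality}-d{self.delay_years}"

    @property
    def family_id(self) -> str:
        """Scenario family = everything but the delay (common-random-number unit)."""
        if self.is_no_screening:
            return f"{self.birth_year}-noscreen"
        return f"{self.birth_year}-{self.frequency_years}y-{self.modality}"


@dataclass(frozen=True)
class ScreenEvent:
    calendar_year: int
    age_years: int
    modality: Modality


@dataclass(frozen=True)
class Schedule:
    """Dated list of routine primary screens for one scenario cell."""

    spec: ScenarioSpec
    events: tuple[ScreenEvent, ...]

    @property
    def delay_window(self) -> tuple[int, int]:
        """Half-open calendar window [2020, 2020 + delay) with no screening."""
        y0 = self.spec.policy.disruption_start_year
        return (y0, y0 + self.spec.delay_years)

    def event_months(self, cycle_months: int = 1) -> list[int]:
        """Event ages as month indices (screen at the birthday month)."""
        return [e.age_years * 12 for e in self.events]

    def to_frame(self):
        """Audit export: one row per screen (cell id, year, age, modality)."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "cell_id": self.spec.cell_id,
                    "calendar_year": e.calendar_year,
                    "age": e.age_years,
                    "modality": e.modality,
                }
                for e in self.events
            ]
        )

    def validate(self) -> None:
        lo, hi = self.delay_window
        years = [e.calendar_year for e in self.events]
        if years != sorted(set(years)):
            raise ValueError("schedule events must be strictly increasing in time")
        pol = self.spec.policy
        for e in self.events:
            if e.calendar_year - e.age_years != self.spec.birth_year:
                raise ValueError("event age inconsistent with birth year")
            if not (pol.start_age <= e.age_years <= pol.stop_age):
                raise ValueError(f"event at age {e.age_years} outside eligible ages")
            if lo <= e.calendar_year < hi:
                raise ValueError(f"event in {e.calendar_year} falls inside the delay window")


def _modality_at(age: int, spec: ScenarioSpec) -> Modality:
    if spec.modality == "HPV_PRIMARY" and age >= spec.policy.hpv_switch_age:
        return "HPV_PRIMARY"
    return "CYTOLOGY"


def build_schedule(spec: ScenarioSpec) -> Schedule:
    """Generate the dated routine-screen list for one scenario cell.

    Pre-2020 screens are placed backward from the 2020 anchor at the cell's
    frequency down to the first age >= ``start_age``; the screen due in 2020
    occurs at 2020 + delay; later screens keep the fixed frequency from that
    shifted anchor; anything landing past ``stop_age`` is dropped.
    """
    if spec.is_no_screening:
        return Schedule(spec, ())
    pol = spec.policy
    f = spec.frequency_years
    by = spec.birth_year
    years: list[int] = []
    # history: backward from the would-be 2020 screen (exclusive)
    y = pol.disruption_start_year - f
    while y - by >= pol.start_age:
        if y - by <= pol.stop_age:
            years.append(y)
        y -= f
    years.reverse()
    # resumption: delayed anchor, then fixed frequency
    y = pol.disruption_start_year + spec.delay_years
    while y - by <= pol.stop_age:
        if y - by >= pol.start_age:
            years.append(y)
        y += f
    events = tuple(ScreenEvent(y, y - by, _modality_at(y - by, spec)) for y in years)
    sched = Schedule(spec, events)
    sched.validate()
    return sched


def last_routine_screen_age(schedule: Schedule) -> int:
    """Age at the final routine screen, or :data:`NO_SCREENS` if none."""
    if not schedule.events:
        return NO_SCREENS
    return max(e.age_years for e in schedule.events)


def build_grid(
    cohorts: Iterable[int] = DEFAULT_COHORTS,
    frequencies: Iterable[int] = DEFAULT_FREQUENCIES,
    modalities: Iterable[Modality] = MODALITIES,
    delays: Iterable[int] = DEFAULT_DELAYS,
    policy: PolicyRules | None = None,
) -> list[ScenarioSpec]:
    """Full cross-product of scenario cells plus per-cohort no-screening
    references (appended last). Defaults give 96 cells + 3 references."""
    policy = policy or PolicyRules()
    cohorts = list(cohorts)
    specs = [
        ScenarioSpec(by, f, m, d, policy)
        for by in cohorts
        for f in frequencies
        for m in modalities
        for d in delays
    ]
    specs.extend(ScenarioSpec.no_screening(by, policy) for by in cohorts)
    return specs
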