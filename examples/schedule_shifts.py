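"""How a pandemic delay reshapes a woman's routine-screening schedule.

Builds the schedule for a woman born in 1975 who screens every 10 years with
cytology (aligned so a screen was due in 2020) under each delay scenario and
prints the screen dates. The printed last-screen ages (65 with no delay;
56/57/60 under 1/2/5-year delays) show the "missed final screen" effect:
post-delay screens keep the fixed frequency, and anything past age 65 is
dropped rather than moved.
"""

from cervisim import ScenarioSpec, build_schedule, last_routine_screen_age

for delay in (0, 1, 2, 5):
    spec = ScenarioSpec(birth_year=1975, frequency_years=10, modality="CYTOLOGY", delay_years=delay)
    schedule = build_schedule(spec)
    dates = ", ".join(f"{e.calendar_year}(age {e.age_years})" for e in schedule.events)
    print(f"delay {delay}y: {dates}")
    print(f"  -> last routine screen at age {last_routine_screen_age(schedule)}")
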