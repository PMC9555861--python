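"""Inspect individual simulated life courses.

Simulates women born 1965 screening 5-yearly with cytology under a 1-year
delay and prints the first trajectory that develops cervical disease: the
dated state changes (HPV acquisition, precancer, progression) and the
screening events along the way. Ages are in months since birth.
"""

from cervisim import ScenarioSpec, StateLabel, build_schedule, simulate_life_course
from cervisim.natural_history import WomanRNG
from cervisim.rng import woman_key
from cervisim.synthetic_params import default_demography, default_variant

schedule = build_schedule(ScenarioSpec(1965, 5, "CYTOLOGY", 1))
params = default_variant("short_dwell")
demography = default_demography()

for i in range(500):
    traj = simulate_life_course(
        schedule, params, demography, rng=WomanRNG(woman_key(2024, 0, i))
    )
    if any(s.label is StateLabel.PRECANCER for _, s in traj.state_path):
        print(f"woman #{i} (born {traj.birth_year}):")
        print(traj.to_frame().to_string(index=False))
        for entry in traj.screen_log:
            print(" ", entry)
        if traj.diagnosis:
            d = traj.diagnosis
            print(f"  diagnosed at age {d.age_months / 12:.1f}y, mode {d.mode.value}")
        print(f"  end: age {traj.end.age_months / 12:.1f}y ({traj.end.reason})")
        break
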