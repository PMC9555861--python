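"""Synthetic parameter generator: dwell targets, risk band, determinism."""

import numpy as np
import pytest

from cervisim.cohort import cohort_solve
from cervisim.natural_history import dwell_time_summary
from cervisim.scenarios import ScenarioSpec, build_schedule
from cervisim.synthetic_params import (
    DEFAULT_VARIANT_SPECS,
    VariantSpec,
    make_variant,
    make_vaccination_profile,
    write_default_inputs,
    DATA_DIR,
)

TARGET_DWELL = {"short_dwell": 10.0, "medium_dwell": 15.0, "long_dwell": 20.0}


def test_variant_spec_validation():
    with pytest.raises(ValueError):
        VariantSpec("bad", 10.0, occult_fraction=0.5)
    with pytest.raises(ValueError):
        VariantSpec("bad", -1.0)


def test_dwell_targets_and_ordering(variants):
    dwells = {name: dwell_time_summary(p)["total_years"] for name, p in variants.items()}
    for name, target in TARGET_DWELL.items():
        assert dwells[name] == pytest.approx(target, rel=0.05)
    assert dwells["short_dwell"] < dwells["medium_dwell"] < dwells["long_dwell"]


def test_occult_only_in_short_variant(variants):
    assert variants["short_dwell"].occult_fraction > 0
    assert variants["medium_dwell"].occult_fraction == 0
    assert variants["long_dwell"].occult_fraction == 0


@pytest.mark.parametrize("name", list(DEFAULT_VARIANT_SPECS))
def test_no_screening_risk_in_plausible_band(name, variants, demography):
    """Every shipped variant yields a non-degenerate epidemic with
    no-screening lifetime risk in the 0.5-2% band."""
    sol = cohort_solve(build_schedule(ScenarioSpec.no_screening(1975)), variants[name], demography)
    assert 0.005 <= sol.lifetime_risk <= 0.02


def test_regeneration_determinism(tmp_path):
    """Same seed regenerates the shipped parameter files byte-for-byte."""
    written = write_default_inputs(tmp_path, seed=0)
    for path in written:
        shipped = DATA_DIR / path.name
        assert shipped.exists(), f"missing shipped fixture {path.name}"
        assert path.read_bytes() == shipped.read_bytes(), path.name


def test_infeasible_target_raises(demography):
    spec = VariantSpec("impossible", 10.0, lifetime_risk_target=0.9)
    with pytest.raises(RuntimeError, match="cannot reach"):
        make_variant(spec, demography=demography)


def test_demography_shape(demography):
    """Mortality is monotone above age 30; survival to 84 lands in 0.7-0.9;
    the hysterectomy hazard is unimodal in mid-life."""
    death = demography.life_table
    assert np.all(np.diff(death[30:]) >= 0)
    death_m, hyst_m = demography.monthly()
    survival = np.prod(1.0 - death_m)
    assert 0.7 <= survival <= 0.9
    hyst = demography.hysterectomy_table
    peak = int(np.argmax(hyst))
    assert 35 <= peak <= 55
    assert np.all(np.diff(hyst[25:peak]) >= 0) and np.all(np.diff(hyst[peak:70]) <= 0)


def test_zero_mortality_override_all_reach_84(no_risk_demography, params):
    from cervisim.kernel import simulate_cohort

    schedule = build_schedule(ScenarioSpec.no_screening(1975))
    p = params.replace(
        hpv_incidence_16_18=np.zeros_like(params.hpv_incidence_16_18),
        hpv_incidence_other=np.zeros_like(params.hpv_incidence_other),
    )
    sample = simulate_cohort(schedule, p, no_risk_demography, n=2000, master_seed=9)
    assert (sample.death_month == -1).all()


def test_vaccination_profile_defaults():
    assert make_vaccination_profile(1965).coverage == 0.0
    assert make_vaccination_profile(1975).coverage == 0.0
    p85 = make_vaccination_profile(1985)
    assert p85.coverage > 0.0
    custom = make_vaccination_profile(1985, {"coverage": 0.4, "efficacy_16_18": 1.0})
    assert custom.coverage == 0.4 and custom.efficacy_16_18 == 1.0
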