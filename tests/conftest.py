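import numpy as np
import pytest

from cervisim.params import Demography, N_AGES, NaturalHistoryParams
from cervisim.synthetic_params import default_demography, default_variant


@pytest.fixture(scope="session")
def demography() -> Demography:
    return default_demography()


@pytest.fixture(scope="session")
def variants() -> dict[str, NaturalHistoryParams]:
    return {name: default_variant(name) for name in ("short_dwell", "medium_dwell", "long_dwell")}


@pytest.fixture(scope="session")
def medium(variants) -> NaturalHistoryParams:
    return variants["medium_dwell"]


def make_params(**overrides) -> NaturalHistoryParams:
    """Minimal hand-set parameter object for unit tests."""
    defaults = dict(
        variant_name="unit_test",
        hpv_incidence_16_18=np.full(N_AGES, 0.001),
        hpv_incidence_other=np.full(N_AGES, 0.002),
        clearance_16_18=0.02,
        clearance_other=0.02,
        progression_to_precancer_16_18=0.004,
        progression_to_precancer_other=0.001,
        regression_from_precancer_16_18=0.01,
        regression_from_precancer_other=0.01,
        progression_to_cancer=0.005,
        symptomatic_detection_rate=0.02,
    )
    defaults.update(overrides)
    return NaturalHistoryParams(**defaults)


@pytest.fixture()
def params() -> NaturalHistoryParams:
    return make_params()


@pytest.fixture(scope="session")
def no_risk_demography() -> Demography:
    return Demography(np.zeros(N_AGES), np.zeros(N_AGES))


def closed_form_params() -> NaturalHistoryParams:
    """Constant symptomatic cancer-onset hazard of 0.001/yr from age 20,
    realized as acquisition feeding a zero-sojourn chain to diagnosis."""
    h = 1.0 - np.exp(-0.001 / 12.0)
    inc = np.zeros(N_AGES)
    inc[20:] = h
    return make_params(
        variant_name="closed_form",
        hpv_incidence_16_18=inc,
        hpv_incidence_other=np.zeros(N_AGES),
        clearance_16_18=0.0,
        clearance_other=0.0,
        progression_to_precancer_16_18=1.0,
        progression_to_precancer_other=0.0,
        regression_from_precancer_16_18=0.0,
        regression_from_precancer_other=0.0,
        progression_to_cancer=1.0,
        symptomatic_detection_rate=1.0,
        occult_fraction=0.0,
    )
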