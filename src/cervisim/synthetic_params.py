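"""Synthetic parameter sets: three stylized dwell-time variants, demography
tables, and cohort vaccination profiles.

The three variants differ only in rate values, realizing short (~10 y),
medium (~15 y) and long (~20 y) mean total dwell times from HPV acquisition
to symptomatic cancer; the short-dwell variant additionally makes a fraction
of new precancers permanently invisible to cytology ("occult" lesions).
These are stylized stand-ins chosen to reproduce the dwell-time *mechanism*;
they are not calibrated to any registry.

Generation is deterministic: rates follow analytically from the dwell
target, and the only fitted quantity is a single scale on the HPV acquisition
curve, chosen by a deterministic root-find so that the no-screening lifetime
risk of cervical cancer lands on a plausible target (1% by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .params import Demography, N_AGES, NaturalHistoryParams, VaccinationProfile

DATA_DIR = Path(__file__).parent / "data"

#: Stage shares of the total dwell time: infected sojourn, precancer sojourn,
#: preclinical sojourn.
_STAGE_SHARES = (0.4, 0.4, 0.2)
#: Probability an infection exit is progression (rather than clearance).
_PROGRESSION_FRACTION = {"16_18": 0.12, "other": 0.03}
#: Probability a precancer exit is progression (rather than regression).
_CANCER_FRACTION = 0.35

DEFAULT_LIFETIME_RISK_TARGET = 0.01  # no-screening proportion by age 84
_RISK_BAND = (0.005, 0.02)


@dataclass(frozen=True)
class VariantSpec:
    """Declarative description of one dwell-time variant.

    Calibrated natural-history models jointly identify dwell time and
    per-episode test sensitivity from the same observed program
    effectiveness, so the two are strongly negatively correlated across
    models. The variants reproduce that pairing: fast progression with high
    episode cytology sensitivity (plus the occult-lesion feature), slow
    progression with low episode sensitivity. Sensitivities sit inside the
    wide published range for cytology detection of CIN2+ (~0.3-0.85).
    """

    name: str
    target_dwell_years: float
    occult_fraction: float = 0.0
    cyto_sens_precancer: float = 0.55
    cyto_sens_cancer: float = 0.80
    lifetime_risk_target: float = DEFAULT_LIFETIME_RISK_TARGET

    def __post_init__(self) -> None:
        if not 0.0 <= self.occult_fraction <= 0.2:
            raise ValueError("occult_fraction must lie in [0, 0.2]")
        if self.target_dwell_years <= 0:
            raise ValueError("dwell target must be positive")


DEFAULT_VARIANT_SPECS = {
    "short_dwell": VariantSpec(
        "short_dwell", 10.0, occult_fraction=0.05,
        cyto_sens_precancer=0.85, cyto_sens_cancer=0.95,
    ),
    "medium_dwell": VariantSpec(
        "medium_dwell", 15.0, cyto_sens_precancer=0.55, cyto_sens_cancer=0.80,
    ),
    "long_dwell": VariantSpec(
        "long_dwell", 20.0, cyto_sens_precancer=0.35, cyto_sens_cancer=0.65,
    ),
}

DEFAULT_VACCINATION = {1965: 0.0, 1975: 0.0, 1985: 0.35}
DEFAULT_VACCINE_EFFICACY = 0.95


def _acquisition_curve() -> np.ndarray:
    """Annual HPV acquisition hazard by age: peaks in the early 20s and
    declines slowly with age (asymmetric Gaussian), zero before age 13."""
    ages = np.arange(N_AGES, dtype=float)
    sigma = np.where(ages < 22.0, 4.0, 12.0)
    curve = np.exp(-0.5 * ((ages - 22.0) / sigma) ** 2)
    curve[ages < 13.0] = 0.0
    return curve


def make_demography(seed: int = 0) -> Demography:
    """Gompertz-style other-cause mortality and a unimodal mid-life benign
    hysterectomy hazard. Deterministic; the seed is accepted for interface
    symmetry and recorded nowhere because nothing here is sampled."""
    ages = np.arange(N_AGES, dtype=float)
    annual_death = 5e-4 + 2e-5 * np.exp(0.08 * ages)
    monthly_death = 1.0 - (1.0 - annual_death) ** (1.0 / 12.0)
    annual_hyst = 0.009 * np.exp(-0.5 * ((ages - 45.0) / 9.0) ** 2)
    annual_hyst[(ages < 20) | (ages > 70)] = 0.0
    monthly_hyst = 1.0 - (1.0 - annual_hyst) ** (1.0 / 12.0)
    return Demography(life_table=monthly_death, hysterectomy_table=monthly_hyst)


def _variant_rates(spec: VariantSpec) -> dict:
    t_inf, t_pre, t_pc = (s * spec.target_dwell_years * 12.0 for s in _STAGE_SHARES)
    r_inf, r_pre, r_pc = 1.0 / t_inf, 1.0 / t_pre, 1.0 / t_pc
    f2 = _CANCER_FRACTION
    out = {
        "progression_to_cancer": f2 * r_pre,
        "symptomatic_detection_rate": r_pc,
        "occult_fraction": spec.occult_fraction,
    }
    for tag, f1 in _PROGRESSION_FRACTION.items():
        out[f"progression_to_precancer_{tag}"] = f1 * r_inf
        out[f"clearance_{tag}"] = (1.0 - f1) * r_inf
        out[f"regression_from_precancer_{tag}"] = (1.0 - f2) * r_pre
    return out


def make_variant(
    spec: VariantSpec | str,
    seed: int = 0,
    demography: Demography | None = None,
) -> NaturalHistoryParams:
    """Build one internally consistent parameter set.

    Rates are derived analytically from the dwell target (geometric stage
    means sum exactly to the target), then the acquisition-curve amplitude is
    fitted so the no-screening lifetime risk under ``demography`` equals the
    variant's target. Deterministic given its inputs.
    """
    from .cohort import cohort_solve  # local import: cohort depends on params only
    from .scenarios import ScenarioSpec, build_schedule

    if isinstance(spec, str):
        spec = DEFAULT_VARIANT_SPECS[spec]
    demography = demography or make_demography(seed)
    curve = _acquisition_curve()
    rates = _variant_rates(spec)
    schedule = build_schedule(ScenarioSpec.no_screening(1975))

    def params_for(peak_annual: float) -> NaturalHistoryParams:
        monthly = 1.0 - (1.0 - np.minimum(peak_annual * curve, 0.6)) ** (1.0 / 12.0)
        return NaturalHistoryParams(
            variant_name=spec.name,
            hpv_incidence_16_18=0.3 * monthly,
            hpv_incidence_other=0.7 * monthly,
            cyto_sens_precancer=spec.cyto_sens_precancer,
            cyto_sens_cancer=spec.cyto_sens_cancer,
            **rates,
            metadata={
                "generator": "cervisim.synthetic_params",
                "stylized": True,
                "dwell_target_years": spec.target_dwell_years,
                "lifetime_risk_target": spec.lifetime_risk_target,
                "seed": seed,
                "acquisition_peak_annual": float(peak_annual),
            },
        )

    def risk_gap(log_peak: float) -> float:
        sol = cohort_solve(schedule, params_for(float(np.exp(log_peak))), demography)
        return sol.lifetime_risk - spec.lifetime_risk_target

    try:
        log_peak = brentq(risk_gap, np.log(1e-3), np.log(0.5), xtol=1e-4, rtol=1e-12)
    except ValueError as err:
        raise RuntimeError(
            f"variant {spec.name!r}: cannot reach lifetime-risk target "
            f"{spec.lifetime_risk_target} within the admissible acquisition range"
        ) from err
    return params_for(float(np.exp(log_peak)))


def make_vaccination_profile(birth_year: int, config: dict | None = None) -> VaccinationProfile:
    """Cohort vaccination: zero for the 1965/1975 cohorts, configurable
    catch-up coverage for 1985 (default 35%, 16/18 efficacy 95%)."""
    config = config or {}
    coverage = config.get("coverage", DEFAULT_VACCINATION.get(birth_year, 0.0))
    efficacy = config.get("efficacy_16_18", DEFAULT_VACCINE_EFFICACY)
    return VaccinationProfile(birth_year=birth_year, coverage=coverage, efficacy_16_18=efficacy)


# ---------------------------------------------------------------------------
# Shipped fixtures
# ---------------------------------------------------------------------------

def write_default_inputs(outdir: str | Path, seed: int = 0) -> list[Path]:
    """Regenerate the parameter files shipped with the package."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    demography = make_demography(seed)
    p = outdir / "demography.csv"
    demography.to_csv(p)
    written.append(p)
    for name, spec in DEFAULT_VARIANT_SPECS.items():
        params = make_variant(spec, seed=seed, demography=demography)
        p = outdir / f"{name}.yaml"
        params.to_yaml(p)
        written.append(p)
    p = outdir / "vaccination.yaml"
    p.write_text(
        yaml.safe_dump(
            {
                "efficacy_16_18": DEFAULT_VACCINE_EFFICACY,
                "coverage": {int(k): float(v) for k, v in DEFAULT_VACCINATION.items()},
            }
        )
    )
    written.append(p)
    return written


def default_demography() -> Demography:
    path = DATA_DIR / "demography.csv"
    if path.exists():
        return Demography.from_csv(path)
    return make_demography()


def default_variant(name: str) -> NaturalHistoryParams:
    path = DATA_DIR / f"{name}.yaml"
    if path.exists():
        return NaturalHistoryParams.from_yaml(path)
    return make_variant(name)


def default_vaccination(birth_year: int) -> VaccinationProfile:
    path = DATA_DIR / "vaccination.yaml"
    if path.exists():
        cfg = yaml.safe_load(path.read_text())
        return VaccinationProfile(
            birth_year=birth_year,
            coverage=cfg["coverage"].get(birth_year, 0.0),
            efficacy_16_18=cfg["efficacy_16_18"],
        )
    return make_vaccination_profile(birth_year)
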