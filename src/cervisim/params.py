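"""Parameter containers: natural-history rates, test characteristics,
demography tables, and cohort vaccination profiles.

All event probabilities are per monthly cycle. Age-indexed inputs are stored
per year of age 0..84 and expanded to a monthly grid (0..1007) by the
engines. Files round-trip through YAML (parameters) and CSV (tables).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MAX_AGE_YEARS = 84
N_AGES = MAX_AGE_YEARS + 1          # per-year tables 0..84
N_MONTHS = MAX_AGE_YEARS * 12       # life course simulated over months 0..1007

PARAM_SCHEMA_VERSION = 1


def _check_prob(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Monthly transition probabilities and test characteristics for one
    stylized model variant.

    Sojourns are geometric: a state with total monthly exit probability *r*
    has mean sojourn 1/r months, and because the geometric clock is
    memoryless the sojourn conditional on which exit occurred has the same
    mean. A probability of exactly 1.0 denotes deterministic, zero-sojourn
    passage through the state (used only by degenerate test configurations).
    """

    variant_name: str
    # age-indexed (85,) monthly acquisition probabilities per genotype group
    hpv_incidence_16_18: np.ndarray
    hpv_incidence_other: np.ndarray
    # scalar monthly probabilities
    clearance_16_18: float
    clearance_other: float
    progression_to_precancer_16_18: float
    progression_to_precancer_other: float
    regression_from_precancer_16_18: float
    regression_from_precancer_other: float
    progression_to_cancer: float
    symptomatic_detection_rate: float
    occult_fraction: float = 0.0
    # test characteristics
    cyto_sens_precancer: float = 0.55
    cyto_sens_cancer: float = 0.80
    cyto_spec: float = 0.97
    hpv_sens: float = 0.92
    hpv_spec: float = 0.91
    hpv_false_pos_16_18_fraction: float = 0.25
    colposcopy_sens: float = 0.95
    colposcopy_compliance: float = 0.79
    treatment_compliance: float = 0.73
    vaccine_efficacy_16_18: float = 0.95
    cycle_length_months: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("hpv_incidence_16_18", "hpv_incidence_other"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_AGES,):
                raise ValueError(f"{name} must have shape ({N_AGES},)")
            object.__setattr__(self, name, arr)
        for name, val in self._scalar_probs().items():
            _check_prob(name, val)
        _check_prob("hpv_incidence_16_18", self.hpv_incidence_16_18)
        _check_prob("hpv_incidence_other", self.hpv_incidence_other)
        if self.cycle_length_months != 1:
            raise ValueError("only monthly cycles are supported")
        # per-cycle event probabilities must form a stochastic row
        for g in ("16_18", "other"):
            tot = getattr(self, f"clearance_{g}") + getattr(self, f"progression_to_precancer_{g}")
            if tot > 1.0 + 1e-12:
                raise ValueError(f"infected-state exit probabilities for {g} exceed 1")
            tot = getattr(self, f"regression_from_precancer_{g}") + self.progression_to_cancer
            if tot > 1.0 + 1e-12:
                raise ValueError(f"precancer-state exit probabilities for {g} exceed 1")

    def _scalar_probs(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "clearance_16_18", "clearance_other",
                "progression_to_precancer_16_18", "progression_to_precancer_other",
                "regression_from_precancer_16_18", "regression_from_precancer_other",
                "progression_to_cancer", "symptomatic_detection_rate", "occult_fraction",
                "cyto_sens_precancer", "cyto_sens_cancer", "cyto_spec",
                "hpv_sens", "hpv_spec", "hpv_false_pos_16_18_fraction",
                "colposcopy_sens", "colposcopy_compliance", "treatment_compliance",
                "vaccine_efficacy_16_18",
            )
        }

    def replace(self, **kw) -> "NaturalHistoryParams":
        return replace(self, **kw)

    # ---- persistence -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["hpv_incidence_16_18"] = [float(x) for x in self.hpv_incidence_16_18]
        d["hpv_incidence_other"] = [float(x) for x in self.hpv_incidence_other]
        d["schema_version"] = PARAM_SCHEMA_VERSION
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        d = dict(d)
        version = d.pop("schema_version", PARAM_SCHEMA_VERSION)
        if version != PARAM_SCHEMA_VERSION:
            raise ValueError(f"unsupported parameter schema version {version}")
        d["hpv_incidence_16_18"] = np.asarray(d["hpv_incidence_16_18"], dtype=float)
        d["hpv_incidence_other"] = np.asarray(d["hpv_incidence_other"], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path_or_text: str | Path) -> "NaturalHistoryParams":
        p = Path(path_or_text)
        text = p.read_text() if p.exists() else str(path_or_text)
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class Demography:
    """Age-indexed monthly competing-risk probabilities (other-cause death,
    benign hysterectomy), per year of age 0..84."""

    life_table: np.ndarray
    hysterectomy_table: np.ndarray

    def __post_init__(self) -> None:
        for name in ("life_table", "hysterectomy_table"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_AGES,):
                raise ValueError(f"{name} must have shape ({N_AGES},)")
            _check_prob(name, arr)
            object.__setattr__(self, name, arr)

    def monthly(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand per-year monthly probabilities onto the month grid."""
        idx = np.arange(N_MONTHS) // 12
        return self.life_table[idx], self.hysterectomy_table[idx]

    def to_csv(self, path: str | Path | None = None) -> str:
        df = pd.DataFrame(
            {
                "age": np.arange(N_AGES),
                "monthly_death_prob": self.life_table,
                "monthly_hysterectomy_prob": self.hysterectomy_table,
            }
        )
        if path is not None:
            df.to_csv(path, index=False)
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path: str | Path) -> "Demography":
        df = pd.read_csv(path)
        df = df.sort_values("age")
        return cls(
            life_table=df["monthly_death_prob"].to_numpy(),
            hysterectomy_table=df["monthly_hysterectomy_prob"].to_numpy(),
        )


@dataclass(frozen=True)
class VaccinationProfile:
    """Cohort-level HPV vaccination: coverage fraction and 16/18 efficacy."""

    birth_year: int
    coverage: float = 0.0
    efficacy_16_18: float = 0.95

    def __post_init__(self) -> None:
        _check_prob("coverage", self.coverage)
        _check_prob("efficacy_16_18", self.efficacy_16_18)


UNVACCINATED = VaccinationProfile(birth_year=0, coverage=0.0)
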