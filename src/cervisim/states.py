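"""Health-state vocabulary shared by the microsimulation and the cohort solver.

The model tracks a woman through HPV acquisition, precancer (CIN2/3 merged),
preclinical invasive cancer, and diagnosis, alongside two competing absorbing
events (other-cause death; benign hysterectomy, which removes the cervix and
hence ends cervical natural history). Genotype distinguishes HPV16/18 from the
pooled other high-risk types, because management rules refer only to that
split. The ``occult`` flag marks lesions that cytology can never see (they sit
deeper in the cervical canal); they remain detectable through HPV testing and
colposcopy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace


class StateLabel(enum.Enum):
    HEALTHY = "HEALTHY"
    HPV_INFECTED = "HPV_INFECTED"
    PRECANCER = "PRECANCER"
    PRECLINICAL_CANCER = "PRECLINICAL_CANCER"
    DIAGNOSED_CANCER = "DIAGNOSED_CANCER"
    HYSTERECTOMY = "HYSTERECTOMY"
    DEAD_OTHER = "DEAD_OTHER"


class Genotype(enum.Enum):
    HPV16_18 = "HPV16_18"
    OTHER_HR = "OTHER_HR"
    NONE = "NONE"


class DetectionMode(enum.Enum):
    SCREEN_DETECTED = "SCREEN_DETECTED"
    SYMPTOMATIC = "SYMPTOMATIC"


#: Labels a woman can never leave (HYSTERECTOMY is absorbing for cervical
#: events; other-cause death still applies to her in the life-course engines).
ABSORBING_LABELS = frozenset(
    {StateLabel.DIAGNOSED_CANCER, StateLabel.DEAD_OTHER, StateLabel.HYSTERECTOMY}
)

#: Labels for which genotype must be NONE.
GENOTYPE_FREE_LABELS = frozenset(
    {StateLabel.HEALTHY, StateLabel.HYSTERECTOMY, StateLabel.DEAD_OTHER}
)

LESION_LABELS = frozenset({StateLabel.PRECANCER, StateLabel.PRECLINICAL_CANCER})


@dataclass(frozen=True)
class HealthState:
    """One woman's instantaneous health state.

    ``surveillance_months_left`` > 0 means a lesion was found at colposcopy but
    not (yet) treated; the woman is under annual surveillance and skips routine
    screening until resolved. ``followup_months_left`` > 0 means a positive
    primary HPV test with negative triage cytology put her on a 12-month
    repeat-HPV follow-up. At most one of the two clocks can be active.
    """

    label: StateLabel = StateLabel.HEALTHY
    genotype: Genotype = Genotype.NONE
    occult: bool = False
    surveillance_months_left: int = 0
    followup_months_left: int = 0

    def __post_init__(self) -> None:
        if (self.genotype is Genotype.NONE) != (self.label in GENOTYPE_FREE_LABELS):
            raise ValueError(
                f"genotype {self.genotype.value} inconsistent with label {self.label.value}"
            )
        if self.occult and self.label not in LESION_LABELS:
            raise ValueError("occult flag allowed only for PRECANCER/PRECLINICAL_CANCER")
        if self.surveillance_months_left and self.label not in LESION_LABELS:
            raise ValueError("surveillance applies only to detected lesions")
        if self.followup_months_left and self.label in ABSORBING_LABELS:
            raise ValueError("follow-up applies only to non-absorbing states")
        if self.followup_months_left and self.surveillance_months_left:
            raise ValueError("surveillance and follow-up clocks are mutually exclusive")

    @property
    def is_absorbing(self) -> bool:
        return self.label in ABSORBING_LABELS

    @property
    def screen_eligible(self) -> bool:
        """Alive, cervix in place, no diagnosed cancer, on the routine track
        (no pending surveillance or follow-up visit)."""
        return (
            not self.is_absorbing
            and self.surveillance_months_left == 0
            and self.followup_months_left == 0
        )

    def with_(self, **kw) -> "HealthState":
        return replace(self, **kw)


HEALTHY = HealthState()
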