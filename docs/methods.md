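# Methods

`cervisim` quantifies how a temporary, pandemic-style suspension of primary
cervical screening redistributes cervical-cancer risk across women with
different screening histories. It combines four pieces: a stylized HPV
natural-history model (two engines — a per-woman Monte Carlo microsimulation
and an exactly equivalent deterministic cohort solver), a screening cascade
with imperfect compliance, a schedule generator encoding the disruption
scenarios, and outcome statistics.

## Disease model

The natural history is a discrete-time multistate model over monthly cycles:

```
HEALTHY <-> HPV_INFECTED(16/18 | other high-risk) <-> PRECANCER(CIN2/3)
        -> PRECLINICAL_CANCER -> DIAGNOSED (screen-detected | symptomatic)
```

with other-cause death and benign hysterectomy as competing events in every
cycle. Within a cycle, a single uniform draw is partitioned in a fixed
priority order — death, hysterectomy, then the state's disease events — so
the event probabilities are absolute per-cycle probabilities and a state's
"row" must sum to at most one (validated). Sojourns are geometric: a state
with total monthly exit probability *r* has mean sojourn 1/*r* months, and
because the geometric clock is memoryless this is also the mean conditional
on which exit occurs. Genotype is dichotomized into HPV16/18 versus pooled
other high-risk types — the only split the management rules use; low-risk
types are not modeled. There is no natural immunity: cleared women return to
the susceptible pool. Treated precancers return to HEALTHY with the causal
infection removed and no residual risk elevation.

A monthly cycle (rather than the annual step common in cohort models) is
required because a 1-year delay must be resolvable against 1-year screening
intervals without aliasing.

*Deterministic-passage convention.* A per-cycle transition probability of
exactly 1.0 is interpreted as zero sojourn: the chain is transited within
the same cycle. Realistic parameter sets never contain exact 1.0, so normal
dynamics are untouched; the convention exists so that degenerate
configurations (e.g. a constant diagnosis hazard used for closed-form
verification) behave as the closed form assumes.

*Ordering within a cycle.* The disease phase runs first; screening,
surveillance and follow-up visits second. A woman who presents
symptomatically in a cycle therefore skips that cycle's screen (a
symptomatic diagnosis never coincides with an attended screen), and a
screening program with all sensitivities and false-positive rates at zero
reproduces the no-screening risk *exactly*, not just approximately.

## Screening cascade

Two primary modalities:

* **Cytology** (ages 21–65): ASCUS+ results get reflex high-risk HPV
  testing; only reflex-positive women are referred to colposcopy.
* **Primary HPV with partial genotyping** (cytology until the first screen
  at age ≥ 30, HPV thereafter): HPV16/18 positives are referred directly;
  other-high-risk positives are triaged with cytology and referred on
  ASCUS+.

Referred women attend colposcopy with probability 0.79; colposcopy detects a
present lesion with probability 0.95 (a design default; near-perfect);
detected precancers are treated with probability 0.73. A detected,
untreated precancer enters **annual surveillance** (re-managed every 12
months until treated, progressed, or regressed). Any HPV-positive episode
that is *not* resolved by colposcopy management — triage-negative,
colposcopy declined, colposcopy negative, or a lesion missed — puts the
woman on an **annual repeat-HPV track**: she is retested every 12 months and
goes to colposcopy while still positive, returning to routine screening
after a negative test. This persistence follow-up is the guideline-faithful
mechanism behind primary HPV screening's safety margin: most at-risk women
(persistent infections) are under annual management, and that management —
like surveillance and diagnostic work-up — is assumed *unaffected* by the
screening disruption.

Occult lesions (a configurable fraction of new precancers, used by the
short-dwell variant) are never visible to cytology, primary or triage, but
remain detectable by HPV testing and colposcopy. Repeat-cytology triage
arms, co-testing, CIN1 management, cancer staging and cancer mortality are
out of scope.

## Delay scenarios

Schedules are anchored backward from the disruption year (2020): cohorts
born 1965/1975/1985 are aligned so a screen was due in 2020, exactly one
inter-screen interval (1, 3, 5, or 10 years) after the previous screen.
A delay of *d* ∈ {0, 1, 2, 5} years suspends 100% of primary screening in
[2020, 2020 + *d*); the delayed screen happens at 2020 + *d* and subsequent
screens keep the pre-pandemic frequency from the shifted anchor. Screens
landing outside ages 21–65 are dropped, never moved — the only reading
consistent with the published last-screen ages (65 → 56/57/60 for the
decennial screener; 65 → 61 for the quinquennial under a 1-year delay).
Routine attendance is deterministic; surveillance and follow-up visits
continue through the delay window. The default grid is 3 cohorts × 4
frequencies × 2 modalities × 4 delays = 96 cells plus 3 no-screening
references, crossed with 3 natural-history variants.

## Two engines, one process

The **microsimulation** simulates each woman month-by-month with
counter-based random numbers: every uniform is a pure function of
(woman key, stream, counter), with separate streams for disease shocks
(counter = month index), occult assignment, the screening cascade, and
vaccination. Because disease shocks are indexed by month and the woman key
excludes the delay arm, all delay arms of a scenario family share their
shock sequences (common random numbers), so arm differences isolate the
delay effect. The engine exists twice: a readable per-woman reference
driver composed of the public `step` / `perform_screen` / `manage_positive`
operations, and a numba kernel for large cohorts; the two are tested to be
bit-for-bit identical.

The **cohort solver** forward-propagates the full state distribution over
an expanded state space (surveillance and follow-up clocks are part of the
state; 242 states) through the same phase structure with the same episode
probabilities. It is deterministic and exact, and serves as the
verification oracle: microsimulation estimates of lifetime risk and
within-window incidence must sit within 3 Monte Carlo SE of the solver on
every grid cell. Vaccinated and unvaccinated strata are solved separately
and mixed by coverage (the dynamics are linear in the initial mass), which
makes e.g. "coverage 0.4 at full efficacy removes exactly 40% of 16/18
risk" an exact identity rather than an approximation. Two deliberate
simplifications, irrelevant to every reported outcome: hysterectomy is
absorbing in the solver (later other-cause deaths of hysterectomized women
are not tracked), and diagnosed women are not followed beyond diagnosis.

## Outcomes

* **Short-term:** symptomatically detected cancers during the half-open
  delay window, per 100,000 women alive, cancer-free and cervix-intact at
  window start; rate ratios against the same-delay guidelines-compliant
  screener (3-yearly cytology or 5-yearly HPV), averaged over the three
  cohorts. Delay-0 cells have no window and no rate.
* **Long-term:** lifetime risk (cohort proportion diagnosed by age 84, all
  women in the denominator including competing deaths — this keeps "cases
  per 100,000 women" additive), its change versus the no-delay arm scaled
  to excess cases per 100,000, and percent of no-screening cancers
  prevented. Reported risks are rounded to the nearest 0.001%; internal
  computation is unrounded.

## Synthetic parameters

No real data ship with the package; the generator produces internally
consistent stand-ins, labeled as stylized in their metadata.

* **Demography:** Gompertz-style other-cause mortality (annual probability
  5·10⁻⁴ + 2·10⁻⁵·e^(0.08·age), survival to 84 ≈ 0.78) and a unimodal
  benign-hysterectomy hazard peaking at 0.009/yr around age 45 (lifetime
  fraction ≈ 18%).
* **HPV acquisition:** an asymmetric Gaussian hazard peaking at age 22
  (SD 4 years below the peak, 12 above; zero before 13), split 30%
  HPV16/18 / 70% other high-risk. The amplitude is the single fitted
  quantity: a deterministic root-find scales it so the no-screening
  lifetime risk equals 1% under the default demography (the plausible band
  being 0.5–2%).
* **Dwell-time variants:** total dwell targets of 10 / 15 / 20 years
  (short / medium / long), allocated 40% / 40% / 20% to the infected,
  precancer and preclinical stages, so the stage rates follow analytically
  and the dwell target is met exactly. Progression fractions are 12%
  (16/18) and 3% (other) per infection, and 35% per precancer, giving the
  two genotype groups their different cancer potential.
* **Dwell–sensitivity pairing:** calibrated natural-history models identify
  dwell time and per-episode test sensitivity jointly from the same
  observed program effectiveness, so the two are strongly negatively
  correlated across models; with a single shared sensitivity the
  cross-variant ordering of underscreener rate ratios cannot reproduce the
  published pattern. The variants therefore pair fast progression with high
  episode cytology sensitivity and slow progression with low: short
  0.85/0.95 (precancer/cancer) plus a 5% occult-lesion fraction, medium
  0.55/0.80, long 0.35/0.65 — all inside the wide published range for
  cytology detection of CIN2+ (~0.3–0.85). HPV test characteristics
  (sensitivity 0.92, specificity 0.91) are assay-driven and shared.
* **Vaccination:** zero coverage for the 1965/1975 cohorts; 35% catch-up
  coverage at 95% HPV16/18 efficacy for the 1985 cohort (configurable).

Generation is deterministic: the same seed regenerates the shipped files
byte-for-byte.

## What the synthetic conditions do and do not show

Passing tests demonstrate that the *mechanisms* — dwell time as the
modifier of delay tolerance, the occult-lesion effect, the HPV persistence
buffer, the missed-final-screen edge effect — are implemented coherently
and that the two engines agree exactly. They do not show calibration to any
registry: absolute lifetime risks (~0.2–0.8% across screening cells),
excess cases and rate ratios are of the right order but are not estimates
for any real population, and the published point estimates of the
registry-calibrated models are deliberately not targets.

## Numerical choices and problem sizes

Monthly cycles over ages 0–84 (1,008 cycles). The solver conserves
occupancy mass to 10⁻¹⁰ at every cycle and refuses non-stochastic rows.
Microsimulation cells default to n = 200,000 women (the full 96-cell × 3
variant sweep runs in minutes on one CPU via the numba kernel); property
suites use the cohort solver, which solves a cell in well under a second.
Ties and degenerate inputs: an empty schedule is a valid no-screening cell;
a delay pushing every remaining screen past 65 yields an empty post-delay
tail, not an error; zero rates report infinite sojourns.

## Known limitations

Single-infection dynamics (no coinfection, no type replacement); no
treatment failure or post-treatment risk elevation; no imperfect routine
attendance or catch-up compression after the delay; geometric (memoryless)
sojourns, which understate the age accumulated by long-escaping lesions;
no cancer stage or mortality. The repeat-HPV follow-up is one clock per
woman — a woman cannot simultaneously hold a surveillance and a follow-up
appointment (colposcopy-confirmed management supersedes the repeat track).
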