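# Methods

## Model structure and assumptions

The model is a deterministic cohort state-transition (semi-Markov) model
with 13 health states: normal mucosa; three ordered precancerous lesion
grades (BCH/mD — basal cell hyperplasia merged with mild dysplasia — then
moderate and severe dysplasia); undetected ESCC in TNM stages I–IV;
clinically detected ESCC in TNM stages I–IV; and death. A closed cohort
enters entirely in the normal state at age 15 and is followed in annual
cycles to age 100 or death. Structural assumptions, all inherited from the
original published model this package re-implements:

* no direct progression from normal mucosa to cancer — every case passes
  through the full lesion sequence;
* no regression between health states in natural history (treatment of
  screen-detected dysplasia is the one exception: it returns people to
  normal mucosa with onset risk and duration reset);
* undetected cancer of any stage, and detected TNM I after resection,
  carry background mortality only; detected TNM II–IV add a
  disease-specific annual death probability, composed multiplicatively
  with background mortality as 1 − (1−q_bg)(1−q_dis);
* transitions other than onset and BCH/mD exit are age- and
  duration-independent.

That undetected TNM IV carries no excess mortality is a deliberate oddity
of the inherited structure, kept for fidelity; it inflates the occult
stage-IV pool slightly.

## Hazards

**Onset** (normal → BCH/mD) is piecewise log-linear in transformed age
u = age − A₁ with knots A₁ = 15, A₂ = 40, A₃ = 100 (so U₂ = 25, U₃ = 85 on
the u-scale). Four slope coefficients β₀…β₃ are published for this hazard
but the printed formula is ambiguous about the summation limits of its
knot-correction term and about the role of β₃ (the accompanying text names
only two age segments, while β₂ is published with an SD of exactly zero —
fixed — and β₃ with a nonzero SD — calibrated, so β₃ must have been
active). `OnsetHazardParams.form` therefore selects among the defensible
readings:

| form | below A₂ | at/above A₂ |
|---|---|---|
| `piecewise_offset` (default) | β₀ + β₁u | β₀ + β₂u + U₂(β₁−β₂) + U₃(β₂−β₃) |
| `piecewise_continuous` | β₀ + β₁u | continuous spline, slopes β₂ then β₃ |
| `piecewise_continuous_beta3` | β₀ + β₁u | continuous, slope β₃ |
| `chronological` | continuous spline on raw age | |

The default was chosen by verification: it is the only enumerated reading
whose forward simulation reproduces all published verification values
(truncated prevalences within their printed 95% CIs and trial outcomes
within 20%). It uses all four published coefficients and implies a
log-hazard step of U₃(β₂−β₃) ≈ −0.709 at age 40 (≈2.2%/yr just below the
knot, ≈0.9%/yr above it); the continuous readings produce lesion
prevalences 60–70% above the published predictions. Users wanting a
textbook continuous spline can select it explicitly.

**Early progression** (BCH/mD → MD) decelerates with time-in-state:
log λ₂ = α₀ − α₁·T_d with T_d the completed years in BCH/mD. Because λ₂
decays slowly (α₁ ≈ 0.037/yr), the duration distribution matters; it is
tracked exactly with one annual tunnel compartment per possible duration
(85 tunnels for the full run — no truncation).

**Rates vs probabilities.** The published percentage-valued parameters
(stage progression, detection, disease-specific mortality) are described
in their source as annual *rates*; the engine accordingly converts them
with p = 1 − exp(−r). This reading was also verification-selected: it is
what brings the occult-cancer prevalence inside its printed interval.
`ModelParameters(input_scale="probability")` switches to using them as
probabilities directly.

## Cycle mechanics

Cycle length is one year with no half-cycle correction (the original
model's choice is unstated; annual targets and five-year age bands make
one-year cycles the natural grain). Within a cycle, competing events from
one state (e.g. progression vs detection vs death from an undetected
stage) are mutually exclusive: their annual probabilities are applied
side-by-side, renormalized onto the simplex in the rare case they sum
above one. Occupancy conservation is asserted every cycle to 1e-9.
Clinical detection — first entry into a detected state — is the incidence
event, matching cancer-registry incidence.

Prevalence over an age band is survivor-weighted: occupancy of the named
states summed over every exact age in the band, divided by alive occupancy
summed likewise. Incidence is new detections per person-year alive,
scaled to 100,000.

## Background mortality

The packaged life table is a Gompertz–Makeham parametrization
q(a) = min(1, c + b·e^{ga}) with c = 5·10⁻⁴, b = 4·10⁻⁵, g = 0.095/yr,
giving life expectancy ≈ 74.6 years at birth — the all-cause mortality
level of the Chinese population around 2011, which is what the original
model used via WHO member-state tables. The parametric form has no
infant-mortality hump and no period detail; neither matters above the
simulation's entry age of 15. Any table can be substituted from an
`age,qx` CSV covering ages 0–100.

## Calibration

Each of the 34 default targets — 18 lesion prevalences and 12 ESCC
incidences by age band, plus 4 TNM-stage-at-diagnosis shares — is treated
as an independent binomial observation: k = round(value·n_eff) successes
in n_eff trials, with the model's corresponding output as the success
probability (clipped to [1e-12, 1−1e-12]). The fit score is
GOF = −2 Σ log-likelihood; lower is better. Effective sample sizes are not
published; defaults are 1,000 persons per prevalence or stage target and
100,000 person-years per incidence target (the order of magnitude of the
source cohorts), editable in the targets CSV. The four stage-share values
are *synthetic placeholders* (their source cohort is published only
graphically); they ship in a separate, clearly named file.

The genetic algorithm evolves a population (default 100) of free-parameter
vectors — β₀…β₃, α₀, α₁, MD→SD, the three stage-progression rates and the
four detection rates; SD→TNM-I and the mortalities stay fixed at their
literature values. Parents are selected with probability proportional to
the difference between their GOF and the worst GOF in the population;
pairs undergo single-point crossover with probability 0.80; each offspring
mutates with probability 0.25, changing one uniformly chosen gene — half
the time a uniform redraw within bounds (exploration), half the time a
Gaussian jitter with SD 5% of the bound width (refinement; a pure uniform
redraw gives almost no late-stage convergence). Replacement is μ+λ: the
next generation keeps the best `population_size` of parents plus
offspring, ties resolved toward parents, so the best GOF never worsens;
`elitism=False` switches to pure generational replacement. "Iterations"
count offspring evaluations, so `iterations=0` just scores and ranks the
initial population.

Default parameter bounds follow the published construction — widely
inclusive of reported uncertainty: ±5 published SDs for the hazard
coefficients, a factor of four either way (capped to [0.001, 0.9]) for the
rates, and a narrow [0, 0.01] box for β₂, which the original calibration
held fixed.

Good-fitting sets are those within Δ of the best GOF; the published
selection rule is unstated, so Δ defaults to the 95th percentile of a
χ² distribution with one degree of freedom per target, and is
configurable. Posterior uncertainty uses SIR: independent truncated
normals around the best fit with the published SDs (25% of the point
estimate where no SD is published) as the proposal, likelihoods as
resampling weights, computed overflow-safely by exponentiating
log-likelihoods after subtracting their maximum; the number of unique sets
retained is reported alongside the resample.

## Screening scenarios

A scenario holds a regional onset multiplier (applied to λ₁ only), an
eligible age band, uptake, test sensitivity and specificity, follow-up
length, and the set of screen-detectable states (default MD, SD and all
undetected stages). Two analyses are supported.

*Truncated prevalence*: survivor-weighted prevalences of each lesion class
over the eligible band under the multiplier; "total high-grade lesions" is
severe dysplasia plus undetected cancer.

*Two-arm trial*: the baseline population is the survivor-weighted
cross-section of an unscreened cohort over the eligible ages, with
detected-cancer and death compartments removed (enrollees are alive with
no known cancer); a uniform-age-weighting flag exists. The screening arm
receives a one-time screen: a fraction uptake × sensitivity of each
detectable compartment is found — dysplasia is treated curatively
(returned to normal mucosa, duration reset; re-onset is permitted), occult
cancers move to the matching detected state and count as incident at the
screen (a flag excludes them). Both arms then run forward; cumulative
incidence is cumulative new detections over baseline alive. Specificity
does not alter disease dynamics (no harm model); it only feeds the
false-positive yield reported per screen.

The hazard ratio between arms is the cumulative-hazard ratio
ln(1−CI_screen)/ln(1−CI_control), the proportional-hazards conversion of
cumulative incidences. This convention is pinned by arithmetic: it
reproduces both published hazard ratios exactly to three decimals from
their printed cumulative incidences (−ln 0.9583/−ln 0.9408 = 0.698 for the
observed pair 4.17%/5.92%; −ln 0.9753/−ln 0.9646 = 0.694 for the predicted
pair 2.47%/3.54%), whereas the simple incidence ratio reproduces neither.

## Synthetic-data generator

`make_synthetic_targets` draws binomial targets k/n around a known
parameter set's outputs, enabling parameter-recovery experiments with a
known truth. It emulates only sampling noise: real calibration targets
additionally carry between-region heterogeneity, secular trend,
diagnostic drift and denominators of varying quality, none of which are
modelled. A recovery test passing therefore shows the search machinery
can invert the model under ideal noise, not that real-world targets
identify the parameters. The default recovery set is 13 targets (three
lesion prevalences at two age bands, incidence at three bands, four stage
shares) at n_eff = 10,000.

## Numerical choices

* Conservation tolerance 1e-9 per cycle (violations raise).
* Binomial probabilities clipped to [1e-12, 1−1e-12]; GOF is then finite
  even for empty-disease parameter sets.
* Competing probabilities renormalized only when their sum exceeds 1;
  "stay" mass floored at 0 against rounding.
* The last duration tunnel is absorbing in duration (irrelevant in
  practice: the tunnel count equals the number of cycles).
* μ+λ sorting is stable with parents listed first, so a tied offspring
  never displaces a parent — this makes the no-variation GA limit exactly
  population-preserving and runs bit-reproducibly from a seed.
* All randomness flows through one `numpy` Generator injected top-down;
  fixed seeds reproduce GA and SIR runs exactly.

## Scaled-down problem sizes

The full published calibration ran 100,000 objective evaluations and a
1,000,000-draw SIR. Package defaults keep those numbers available, but the
test suite and examples use scaled-down versions chosen as reasonable
experiment sizes for a laptop-class machine: recovery runs use population
50 with 2,000 evaluations; SIR checks use 10⁴–10⁵ draws; property sweeps
use 200 random parameter draws.

## Known limitations

* With the default onset reading, model incidence plateaus near
  420 per 100,000/yr above age 70 — well below the oldest-age registry
  targets (879–1145 per 100,000). The continuous-spline reading tracks
  those targets to within a factor of two everywhere but then overshoots
  every published verification prevalence. The two published surfaces are
  mutually inconsistent at old ages under any reading we enumerated; the
  package sides with the verification analyses and documents the
  incidence shortfall rather than hiding it.
* A 2,000-evaluation genetic-algorithm run does not reliably reach the
  GOF optimum of the 14-parameter recovery problem: across seeds it lands
  within 2–6 binomial SEs of the synthetic targets, while a long local
  search from the truth shows the optimum itself sits within 1.3 SEs of
  every target. Tight target-space recovery should be expected from the
  full-size search, not the scaled-down one.
* The model is a cohort average: no individual risk factors, no
  birth-cohort or period effects, no regression of lesions, no screening
  harms, and costs/utilities are out of scope.
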