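# Methods

## Overview

`htnsim` simulates hypertension management at the individual level as a
discrete event process. Each person's state — age, risk factors, medication
regimen, control status, CVD history — evolves between events; hazards are
held piecewise constant between state-update boundaries (office visits,
annual birthdays, the end of a strategy's intervention window, and clinical
events), so the time to each candidate event is an exponential draw that is
re-drawn, memorylessly, at every boundary. Competing candidates resolve by
earliest time, with exact ties broken by a fixed priority (death > CVD >
SAE > intolerable AE > visit > birthday > horizon). This re-draw convention
is the standard way to run a DES with time-varying hazards; it is exactly
equivalent to sampling from the piecewise-exponential survival curve, which
the test suite verifies against a one-day-step Bernoulli microsimulation.

## Synthetic cohort

The cohort generator emulates a survey-derived sample of US adults that is
filtered to intensive-BP-trial eligibility and weighted to resemble the
trial's baseline table. Risk factors are drawn from a Gaussian copula with
configurable marginals (normal, lognormal, Bernoulli, categorical) and a
modest pairwise correlation structure (age–SBP +0.20, age–eGFR −0.45,
SBP–DBP +0.50, BMI–diabetes +0.25, …). Eligibility is a data-driven rule
set: age ≥ 50; SBP 130–180 mm Hg with medication-count-dependent caps
(180/180/170/160/150 for 0–4 drugs); elevated CVD risk (any of clinical
CVD, eGFR 20–59, 10-year first-CVD risk ≥ 15% computed from the shipped
hazard models, or age ≥ 75); no diabetes; eGFR ≥ 20.

Two weighting schemes are provided. *Trial-representative* weights come
from iterative proportional fitting (tolerance 1e-8, 1000-iteration cap) on
sex, age bands, SBP bands, clinical CVD, smoking, CKD and Black race, with
targets taken from the trial's published baseline characteristics; the SBP
band targets (40/34/26% across ≤132, 132–145, >145 mm Hg) were chosen so
the weighted baseline mean is ~138.6 mm Hg, the value the full pipeline is
designed to reproduce, given that eligibility truncates the SBP marginal.
*National* weights scale the generator's base weights to 18.1 million
eligible adults; they stand in for survey design weights, which the
synthetic generator does not model.

Each continuous factor carries a deterministic piecewise-linear age
trajectory anchored at its baseline value. SBP drifts +0.8/yr before 60,
+0.5/yr to 70, +0.2/yr to 80 and is flat afterwards — the plateau shape
seen in observed cohort trajectories; early drafts that kept climbing past
75 produced spurious loss of BP control in every arm. DBP declines after
55; eGFR declines faster with age; diabetes is a trajectory too (an
indicator switching on at a pre-drawn exponential onset age, mean waiting
60 years). CKD (eGFR < 60) and ESRD (eGFR < 15) derive from the eGFR
trajectory. What the generator does **not** emulate: survey design
variables, measurement error in the baseline survey itself, secular trends,
and the joint estimation of trajectories from longitudinal data — passing
tests therefore show internal consistency of the pipeline, not fidelity to
any real cohort's microdata.

## Care processes

At every visit the individual's BP is measured with Gaussian error
(unbiased; SD = σ_base/√readings, shrunk exponentially toward a 2 mm Hg
floor at 3% per accumulated visit, representing the improving working
estimate as information accrues), the strategy's goal is re-evaluated
(the JNC 7-style rule tightens to <130/80 if CKD or diabetes has
developed), and if the *measured* BP is at or above goal the regimen is
intensified with a strategy- and period-specific probability. Titration is
start-low-go-slow: four dose sub-steps per medication, dose-up before
adding the next agent, five agents maximum. The first titration step lowers
true SBP by `per_step_sbp_mmhg` (default 8, calibrated) and each successive
step by a factor `dose_response_decay` = 0.93 less — the diminishing-returns
shape of antihypertensive dose-response. Baseline medications enter at full
dose with their effect already embedded in the observed baseline BP, so
only added steps lower BP further. Adherence multiplies the realised
effect. Intolerable adverse events switch a medication without changing the
count; de-intensification after an SAE is available behind a flag, off by
default.

Usual-care physician follow-up is state dependent: 3 months while the last
measurement was uncontrolled, 6 months while controlled. The intensive
protocol schedules visits at months 1, 2, 3 and then quarterly until 3.26
years (the trial's median follow-up), after which all care processes revert
to usual-care values exactly and only the goal is retained. Team-based care
adds nonphysician titration visits every 6 weeks during year 1; an attended
nonphysician visit defers the pending physician follow-up (the usual
state-dependent interval restarts), which is the burden-reduction mechanism
of team-based care and is why it accumulates the fewest physician visits.

## Risk engine

Incident CHD, stroke, HF and non-CVD death hazards are
λ = λ₀(age band, sex) · exp(βᵀx) · HR_treat. The baseline tables are
tabulated at a reference profile (never-smoker, SBP 120, BMI 25, HDL 50,
LDL 110, eGFR ≥ 60) with age and sex entirely in the table, and were set to
reproduce life-table-like all-cause mortality and contemporary CVD
incidence for a trial-eligible (healthier than average) cohort; the
incident-CVD tables are additionally scaled by a calibrated multiplier. The
Cox SBP covariate uses the *untreated* SBP trajectory; medication-induced
lowering enters only through the meta-analytic treatment-effect factors
HR^(ΔSBP/10) (CHD 0.83, stroke 0.73, HF 0.72; non-CVD death 1.0 in the
primary analysis, <1 as a scenario). This separation prevents double
counting of the same mm Hg. Recurrent events and chronic CVD death (both
age/sex lookup tables, active once an individual has CVD history) receive a
composite treatment factor, the type-split-weighted geometric mean of the
three CVD HRs. Every incident or recurrent event is acutely fatal with an
age-band probability; SAE rates and intolerable-AE rates are lookup tables
in the medication count; SAE fatality is an age-band table; all nonfatal
SAEs are counted as hospitalizations.

## Calibration

Five free parameters are tuned to the intensive-BP trial over its 3.26-year
median follow-up: the protocol and usual-care intensification
probabilities, the per-step SBP effect, the measurement-error SD, and the
incident-CVD hazard scale. Targets (with CI-halfwidth scaling in a weighted
least-squares objective): intensive-arm achieved SBP 121.4 (120.9–121.9)
mm Hg, intensive-arm medications 2.8 (2.7–2.9), intensive-arm first-event
rate 1.65 (1.44–1.89) per 100 person-years, standard-arm achieved SBP 134.6
(134.1–135.1) mm Hg. The generic `calibrate()` operation is a
Latin-hypercube screen plus Nelder-Mead refinement with a restart, all with
fixed seeds so proposals share common random numbers and the objective is
deterministic. Because several parameter combinations reproduce the same
achieved SBP, the default pipeline stages the fit into well-identified
sub-problems — (protocol probability, per-step effect) → measurement SD →
usual-care probability → hazard scale (multiplicative refinement) — and
finally tunes the team-based-care intensification probability by bisection
so the paired 1-year SBP reduction versus goal-matched usual care hits the
meta-analytic benchmark of −7.1 (−9.1 to −5.1) mm Hg. The goal-matched
comparator isolates the team-based-care process itself, matching how the
benchmark trials were designed. Staging removed a severe seed-dependence of
the joint 5-D search. A `coverage_check` reports, per target, the fraction
of probabilistic iterations inside the observed CI.

## Outcomes and uncertainty

Iteration summaries carry event counts (partitioned exactly into CHD,
stroke and HF × first/recurrent × fatal/nonfatal, plus SAEs, intolerable
AEs and non-CVD deaths), mean true SBP/DBP and medication count at each
anniversary among survivors, goal attainment at the horizon (true BP below
the individual's current goal), physician and nonphysician visit counts,
undiscounted life years, and healthy life years. Healthy life years
integrate 1 minus the sum of active disability decrements (floored at
zero): chronic conditions persist from onset, acute decrements (CVD event,
SAE, intolerable AE) last one year, and an age decrement applies per decade
over 70. Decrements combine additively — the simplest auditable rule; a
multiplicative combination would give slightly larger HLY under
multimorbidity. Rates are reported per 1000 baseline individuals over the
horizon, and national annual counts scale events by the configured 18.1
million population total divided by the horizon (baseline denominator, not
person-years; a flag selects person-years). Probabilistic analysis re-draws
every distributed registry parameter per iteration — distributions are
dispersion-around-the-current-value (beta for probabilities, gamma or
lognormal for rates and multipliers, normal for effects), so they follow
the calibrated point values — and the 95% uncertainty interval is the
2.5th–97.5th percentile of iteration means under the linear-interpolation
(type-7) quantile convention. All strategies within an iteration share
per-(iteration, individual, purpose) random substreams, so contrasts are
paired differences.

## Problem sizes

The shipped analysis defaults are 25,000 individuals and 200 probabilistic
iterations. The reproduction study used by the test suite and the
acceptance script runs 2000 individuals and 20 iterations with a
6000-individual generator pool and a 1600-individual calibration subsample
— sizes chosen so the full pipeline completes in minutes on one CPU while
keeping Monte-Carlo error well inside the published uncertainty intervals
for the headline outcomes.

## Numerical and design notes

- RNG: all randomness derives from one master seed through named
  substreams keyed by (iteration, individual, purpose); adding an event
  type or purpose does not perturb existing draws, and replays are
  bit-identical.
- Ages in rate tables clamp to the outer bands; covariates clamp to
  physiological bounds before exponentiation; trajectories clamp to the
  18–99 support.
- The lifetime horizon caps simulation at age 100.
- Visit-driven state (control status) updates only at attended visits; a
  configurable no-show probability (default 0) skips clinical actions but
  keeps the schedule.
- The cohort resampler draws with replacement proportional to the active
  weight; repeated draws of one source individual share a trajectory row.

## Known limitations

- No drug-class-specific effects, interactions or class-specific adverse
  events; medication effects are exchangeable averages.
- The per-added-medication SBP effect implied by the trial's arm contrast
  (~15–20 mm Hg under this model's structure) is larger than
  placebo-controlled monotherapy effects; the diminishing dose-response
  partially reconciles the two, but medication-count-linked quantities
  (SAE rates in particular) inherit the tension.
- Team-based care reverts fully to usual care after year 1 except for the
  retained goal, accumulated measurement information and deferred
  physician follow-ups; its long-run separation from usual care is
  therefore smaller here than mechanisms with persistent process effects
  would produce.
- Recurrent events are type-agnostic with a fixed type split; acute case
  fatality does not depend on treatment.
- The synthetic cohort reproduces marginal moments and selected
  correlations, not real survey microdata.
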