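# Methods

`ckdcea` evaluates a multidisciplinary-care (MDC) program for stage 3–4
chronic kidney disease against usual care, from the payer perspective, as a
cost-effectiveness analysis built on calibrated Markov cohort models.  This
note records the model, its assumptions, the numerical choices, and what
the synthetic inputs do and do not represent.

## Disease model

Each subpopulation — a combination of age band (45–64, 65–74, 75–84),
sex, race, baseline eGFR, and albuminuria level (UACR ≈ 1, 300, 1,000 or
3,000 mg/g) — gets its own deterministic Markov cohort model.  The state
space is a ladder of eleven width-5 eGFR bins from [55, 59] down to
[5, 9] ml/min/1.73 m², plus two absorbing states, ESRD and Death.  Cycles
are monthly.  In a cycle a patient may stay, drop exactly one bin (no
stage skipping, no improvement), enter ESRD (only from bins lying entirely
below 15 ml/min/1.73 m²; a configuration switch admits entry from
[15, 19] instead), or die.  ESRD exits only to Death.  UACR is fixed over
a run; age advances by 1/12 year per cycle, with annual life-table rows
looked up at the integer part of age.  A lifetime horizon means simulating
to age 110, terminating early once the cohort is fully absorbed into
Death (the remaining cycles are padded with the constant absorbed
distribution, so downstream horizon queries remain valid).

ESRD cumulative incidence is tallied with an entry counter, not the ESRD
occupancy: people who enter ESRD and later die must still count as ESRD
cases.

## Calibration

Transition probabilities are not taken directly from the literature,
because progression and mortality interact; instead each subpopulation's
model is calibrated to four targets: 2- and 5-year ESRD risk (from a
kidney-failure risk equation of the Tangri type) and 2- and 5-year
all-cause mortality.  The mortality target converts life-table annual
probabilities to a cumulative hazard, multiplies by the subpopulation's
CKD mortality hazard ratio, and back-transforms:
`1 − exp(−HR · Σₐ −ln(1 − qₐ))`.  Mortality targets use the same 2/5-year
horizons as the ESRD targets.  The ESRD state's own monthly death
probability is not calibrated; it comes directly from the annual ESRD
mortality input via the constant-hazard conversion.

The default free-parameter vector has seven entries: one monthly
progression log-odds per CKD stage (3, 4, 5 — KDIGO bin mapping:
stage 3 = bins ≥ 30, stage 4 = [15, 29], stage 5 = < 15), one log hazard
multiplier on life-table monthly mortality per stage, and one monthly
ESRD-entry log-odds shared by the eligible bins.  Tying progression within
stage keeps the 4-target problem from being grossly over-parameterized; an
untied per-bin mode (15 parameters) exists for experimentation.  All
parameters live on an unconstrained scale (logit for probabilities, log
for multipliers), so every decoded candidate is a valid probability;
residual row-sum violations (exit probabilities summing above 1 at some
age) return a finite penalty of 10⁶ plus the violation rather than
raising, so the Nelder–Mead simplex can recover.

The objective is the sum of squared percent differences over the four
targets.  When a target is exactly zero (a zero-ESRD stratum), the percent
difference is undefined and that term falls back to the squared absolute
difference.  Minimization uses Nelder–Mead (adaptive simplex) with
absolute objective and simplex tolerances of 1e-8, at most 5,000
evaluations per start, and 3 perturbed restarts drawn from a seeded
generator; results are deterministic given options.  The hot path is a
jitted kernel that replays the monthly recursion; the readable
cohort-engine path remains the reference implementation and the test
suite asserts their agreement to machine precision.

With targets generated from an in-family truth model the fit recovers the
target incidences to well under 0.5% relative error.  With targets from
the risk equation, most strata fit to numerical zero; strata combining
very high ESRD risk with the ladder's intrinsic arrival delay can retain
a small residual, which `validate_calibration` reports rather than hides —
the published analysis likewise inspected each calibrated model manually.

## Intervention arm

A 100%-effective MDC model is obtained by scaling usual-care monthly
hazards with two scalars — one on death from the eGFR bins, one on
progression plus ESRD entry (`p′ = 1 − (1 − p)^m`, m ∈ (0, 1]) — solved so
that the cohort's cumulative-incidence odds ratios at 4.9 years equal the
published meta-analytic values (base case 0.62 death, 0.59 ESRD).  The
two one-dimensional root finds (Brent, xtol 1e-13) alternate until both
odds-ratio residuals are below 1e-8; cross-coupling through competing
risks is weak, so a handful of sweeps suffices.  ESRD cumulative
incidence for the odds ratio means ever-entered-ESRD by 4.9 years; death
before ESRD counts as no ESRD event.  Protective odds ratios only: values
above 1 are rejected by design.

The ESRD state's mortality is never scaled.  The program stops at ESRD,
and the stage-discounting contract (below) requires the ESRD and Death
rows to be untouched; applying the death multiplier only to the eGFR bins
keeps the full-effect model exactly reproducible as the
effectiveness-1.0 limit of the discounted model.

Stage-specific effectiveness then interpolates transition-wise between
usual care and the full-effect model: `p = p_u + f_stage · (p_f − p_u)`,
with base-case fractions 0.25 / 0.50 / 1.00 for stages 3 / 4 / 5.  The
ESRD-entry transition uses its source bin's stage (always stage 5).  A
multiplier of exactly 1 and a fraction of exactly 0 or 1 are bitwise
identities.  The scenario grid covers scaled fractions (50% and 25% of
base), uniform non-discounted fractions (100/50/25%), and mortality-only
variants, plus cost scenarios (med/lab uptake 0/10/25/50/100%, program
cost ×2 and ×5).

## Economics

Costs are in US dollars; MDC schedule components are carried as integer
cents so itemized totals are exact (first visit $273.11; recurring
$797.10 / $1,484.02 / $2,074.40 per stage-year; medication add-on
$4,552.08/year; laboratory add-on $877.88/year — the laboratory figure is
the row-wise sum of the itemized panel).  Usual-care annual costs vary by
eGFR bin and ESRD.  Utilities are 0.80 for all CKD bins (quality-of-life
evidence does not separate CKD stages) and 0.71 for ESRD.

Accrual applies a standard half-cycle correction — cycle *t*'s reward
weight is the mean of occupancy at cycle starts *t* and *t + 1* — and
discounts at 3%/year through the compound-equivalent monthly factor
`(1.03)^(−t/12)`.  The MDC arm adds the schedule to eGFR-bin occupancy
only (nothing accrues to ESRD), restricts the medication add-on to bins
entirely at or below 30 ml/min/1.73 m² and the laboratory add-on to bins
at or below 45, each weighted by its uptake fraction, and charges the
first-visit cost once at entry, undiscounted and outside the half-cycle
weighting (a one-time event, not a rate).  The ICER is Δcost/ΔQALY
(undefined when ΔQALY ≤ 0); net monetary benefit is
`WTP · ΔQALY − Δcost` at a default willingness to pay of $150,000/QALY.

## Hazard ratios by microsimulation

To express the intervention effect as hazard ratios, 10,000 individuals
per arm walk the monthly chain by categorical sampling (single seeded
generator, vectorized over individuals), and a two-group Cox proportional
hazards model is fitted per outcome with Efron tie handling (the monthly
grid produces heavy ties).  Death right-censors the ESRD analysis — a
cause-specific hazard, since the competing-risk treatment in the source
analysis is unstated.  Under heavy ties (hundreds of events per distinct
grid time) the Efron Wald interval is known to undercover slightly; the
recovery tests therefore use regimes with moderate ties.

## Probabilistic sensitivity analysis

Every uncertain parameter gets a distribution whose central 95% mass
approximates its 95% CI: beta for probabilities and utilities, log-normal
for odds ratios, gamma for costs.  The spread comes from the normal
approximation `sd = (hi − lo)/3.92` (log-scale for the log-normal); the
achieved mass inside the CI is stored as a coverage diagnostic.  Joint
draws preserve marginals while inducing a target Spearman correlation by
Iman–Conover rank reordering.  Parameters in an order group (the 2/5-year
targets of each outcome; the per-bin CKD costs) share one uniform
quantile per draw and are additionally sorted into point-estimate order,
so severity/horizon orderings hold in 100% of draws even where marginal
quantile curves would cross.

Per draw the pipeline re-solves both arms: drawn targets → usual-care
recalibration (warm-started from the base-case fit, no restarts) → MDC
calibration to the drawn odds ratios (clipped at 1: the draw may exceed
1, but the intervention model is protective by design) → stage
discounting → lifetime accrual with drawn utilities and costs.  A draw is
flagged and excluded when its calibration objective exceeds ten times the
base-case objective (the fraction must stay below 1%).  The default run
uses 5,000 draws; the test suite and acceptance script use 500, which is
enough for the structural properties (CEAC monotonicity, order
preservation, quantile-CI consistency, determinism) they assert.
Cost-effectiveness acceptability curves report the fraction of draws with
positive net monetary benefit over a WTP grid of $0–$250,000 in $2,500
steps; confidence intervals are the empirical 2.5%/97.5% quantiles.
Recomputing Cox hazard ratios inside every draw would multiply the cost
per draw by orders of magnitude, so per-draw microsimulation is off by
default and hazard-ratio CIs are reported from the deterministic arms.

## Synthetic inputs

The published analysis consumes literature inputs that are cited but not
reprinted (risk-equation coefficients, national life tables, CKD
mortality hazard ratios, USRDS cost and mortality estimates).  The
synthetic module generates structural stand-ins: a Gompertz life table
(mortality increasing in age, male and race multipliers), a Weibull
ESRD-risk function log-linear in age, sex, eGFR and log-UACR with sign
constraints enforcing the risk gradients, a severity-increasing hazard-
ratio grid clipped to [1, 8], severity-increasing annual CKD costs with an
ESRD cost of $90,000, and age-band ESRD mortality (0.12/0.18/0.25 per
year).  The Weibull shape (default 4) makes early ESRD risk small
relative to 5-year risk, consistent with the arrival delay a
one-bin-per-cycle ladder imposes; coefficients put 5-year ESRD risk from
roughly 0.1% in the lowest-risk strata to tens of percent in the highest.
All coefficients are synthetic — chosen for realistic orders of
magnitude, never estimated from patient data — and must not be used as
clinical estimates.

Truth transition models for recovery testing are built by decoding
stage-level parameters (with seeded log-normal jitter per stratum and a
UACR severity factor) through the same parameterization the calibrator
searches, which guarantees the recovery problem is feasible.

Consequently, passing tests demonstrate that the machinery is correct —
calibration recovers known truths, odds-ratio calibration is exact,
accounting identities hold, PSA properties are structural — not that the
package reproduces the published headline estimates, which would require
the unpublished inputs.  The quantities that are reproducible from the
published tables alone (the itemized MDC cost schedule and the
NMB/ICER/Δcost identities on printed result rows) are reproduced exactly.

## Problem sizes and defaults

Calibration: 5,000 evaluations/start, 3 restarts (recovery suites use
default options; per-draw PSA refits warm-start with no restarts).
Microsimulation: 10,000 individuals per arm for reported hazard ratios.
PSA: 5,000 draws by default; 500 in the test suite and acceptance script.
Recovery sweeps: 50 random strata in the test suite, 25 in the acceptance
script.  The acceptance script's reported quantities are all recomputed
at run time from these components.

## Known limitations

- No eGFR improvement, stage skipping, acute kidney injury, or multiple
  ESRD modalities; ESRD is one state.
- Albuminuria fixed at baseline.
- Adherence is only implicit in the effectiveness estimates and their
  scenario range.
- The "Overall" rows weight strata equally by default; the population
  weights behind the published overall rows are unknown and configurable.
- Hazard-ratio uncertainty is not propagated through the PSA by default
  (see above).
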