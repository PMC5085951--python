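# Methods

This note documents the model implemented by `thacea`, its assumptions,
parameter choices, numerical conventions, and the limits of what the test
suite can demonstrate.

## Decision model

Two arms — immediate total hip arthroplasty (THA) versus nonoperative
care — are compared for a cohort with end-stage hip osteoarthritis over
the remaining lifetime, in one-year cycles with no half-cycle correction.
The public state space is: nonsurgery (an alias of end-stage
osteoarthritis: identical utility and cost, immediate entry), end-stage
osteoarthritis, more severe osteoarthritis, initial post-THA (occupied
only in the surgery year), successful THA, post-first-revision (early vs
late, by when the revision occurred relative to the index surgery),
post-second revision (transitional), and death (absorbing).

Internally the engine splits the revision states further: the *revision
year* is distinguished from *established* residence (so the
second-revision hazard can be higher in the first year after a first
revision than later), and revision years are split by cause
(aseptic/infection) because their annual costs differ (USD 57,141 vs
95,763). Established post-revision years carry the successful-THA
maintenance cost (USD 12,225); no separate chronic post-revision cost is
published, and this choice keeps the cost of a revised-but-stable hip
equal to that of an unrevised one. Post-second revision is
terminal-chronic: one transitional year at the revision cost, then
permanent residence at utility 0.58 with maintenance cost; third
revisions are not modelled.

Death at any transition combines natural mortality q_nat (from the life
table) with surgical mortality q_surg as 1 − (1 − q_nat)(1 − q_surg),
i.e. independent competing risks. Perioperative revision mortality
(0.003 under age 75, 0.012 at 75+) is applied to the mass routed *into* a
revision state on the row that triggers the revision; perioperative
primary-THA mortality applies in the initial post-THA row. The cohort
stops when dead occupancy exceeds 1 − 1e-9 or at the maximum age
(110, where the life table forces q = 1).

Per cycle t the model accrues (1 + r)^(−t) times: the occupancy-weighted
state utility (QALYs), the state's annual direct medical cost, and — in
the THA arm only — the indirect productivity benefit for the cohort's
current age band. The nonoperative arm's productivity is the baseline
against which the benefit is defined, so it accrues zero. The surgery
year instead accrues `first_year_indirect_fraction` (0.50) of the
steady-state gain minus `recovery_missed_days` (40) priced at the band's
daily earnings; the two adjustments are independent parameters because
their interaction is not otherwise constrained. Whether indirect benefits
continue during revision years is not specified by the sources; the
engine continues them at the profile value (they stop at the retirement
age regardless, via the profile).

## Parameters

Base-case values (discount rate 0.03/year; osteoarthritis progression
0.041/year; utilities by state and gender; annual costs; second-revision
rates 0.0583/0.017 early and 0.022/0.006 late for aseptic/infection;
retirement at 75; 300,000 procedures/year) are shipped in
`thacea/data/default_parameters.yaml` with provenance tags. Derived
values are recomputed rather than stored: the post-second-revision
utility is 90% of the post-first-revision utility rounded to two decimals
(the engine uses the rounded 0.58, matching the published presentation),
and the successful-THA cost is the end-stage cost minus a USD 590
osteoarthritis-cost offset. The initial post-THA utility would be a
25%/75% pre/post blend (0.75 male / 0.72 female), but the published
single value 0.74 is used for both genders; the blend fills the value
only when it is absent.

Several cited inputs are not printed anywhere public: perioperative
primary-THA mortality by age band and gender, first-revision rates by
band, the inpatient-sample gender weights, and the age distribution used
to pool the "All" row. These ship as clearly labelled fixture values of
plausible magnitude (provenance `fixture`), constant across bands where
no band detail exists — the first-revision rates use the published
base-case male/female values (early aseptic 1.31%/1.13%, late aseptic
0.61%/0.63%, early infection 0.20%/0.17%, late infection 0.09%) — and are
fully user-overridable through the YAML/CSV configuration. The
consequence is that band-level cohort outputs are indicative, not
reproductions: the worked-example report in the README is the package's
own base case.

Age-varying parameters use the reporting bands 40–49, 50–59, 60–64,
65–69, 70–74, 75+; a band is represented by its midpoint age (45, 55,
62.5, 67.5, 72.5, and 77 for the open band).

## Indirect-cost estimation

Stage 1 is a probit of employment on demographics (age, gender, race,
marital status, family size, education), the seven ordinal
functional-limitation items (0 = no difficulty … 4 = unable), and two
exclusion variables that enter the employment equation only (other income
sources, another worker in the household). Stage 2 regresses log
earnings on the same covariates minus the exclusions plus the inverse
Mills ratio λ(z) = φ(z)/Φ(z) evaluated at the stage-1 index, on employed
records only. λ is computed as exp(logφ − logΦ) for numerical stability
deep in the left tail. The probit uses Newton iterations (tolerance
1e-8, 100 iterations max). Earnings are modelled on the log scale and
retransformed by exp of the conditional mean; the half-residual-variance
smearing adjustment is available but off by default. Two-step standard
errors are the component-model covariances without a generated-regressor
correction — downstream use is point prediction plus bootstrap, so
corrected standard errors are never consumed.

Survey income is multiply imputed (m = 5 by convention); the estimator
fits each imputation separately and pools with Rubin's rules (mean
coefficients; within-imputation variance plus (1 + 1/m) times
between-imputation variance).

Expected productivity for a covariate profile is P(employed) ×
E[earnings | employed] × (1 − missed days / workdays), with 250 workdays
per year as the full-time assumption needed to price a missed day.
Missed days are mapped from the 0–100 functional-limitations index
(100 × Σitems/28) by a monotone linear link, days = 0.96·index − 1.84
clipped to [0, 250], calibrated so the typical pre-surgery index (~54)
gives ~50 missed days and the post-surgery index gives ~14; the
estimation equation behind the published 50 → 14 change is not available,
so only those anchors are matched.

The bootstrap resamples patients with replacement (default 1000
iterations), computes the mean change in expected productivity per
resample, and reports the mean of iteration means with a percentile
(2.5/97.5) interval — percentile rather than normal-theory because the
iteration-mean distribution is used directly. Age × gender profiles are
counterfactual: every patient's age/gender is overwritten with the band
midpoint and gender of interest, because the patient sample is too small
to stratify. Covariates the patient questionnaire does not collect are
fixed at reference values (married, family of two, no college, no other
income, one other household worker).

## Sensitivity analyses

*Threshold*: a single parameter is scaled by a multiplier m and net
societal savings net(m) is bisected to zero on m ∈ [0.1, 10] (tolerance
USD 1 on net savings or bracket 1e-6). Monotonicity is checked by
sampling the endpoints and midpoint; no sign change across the bracket
flags the parameter *robust*. Supported targets: the productivity
profile, any annual cost, and any revision rate (scaled across bands).

*PSA*: each draw samples a patient age (normal, mean 66, SD 10, clipped
to 40–95 and rounded) and gender (42% female), and a productivity
multiplier — logistic for men, lognormal for women, location-scale set so
the multiplier is centred at 1 with spread comparable to the bootstrap
CI — then reruns both arms. Outputs: the incremental (cost, QALY) cloud,
arm-level mean lifetime societal costs with normal-theory 95% CIs of the
mean, the fraction of draws in which surgery is cost saving, and the
confidence ellipse. Restricting sampled uncertainty to the indirect-cost
side is deliberate: direct costs and transition probabilities stay at
base case unless the caller supplies distributions.

*Ellipse*: center = sample means, shape = sample covariance divided by n,
squared radius = χ²(0.95, 2 df) — an ellipse for the *mean*, not a
prediction region for individual draws. Collinear clouds raise an error
rather than returning a degenerate shape.

*Microsimulation*: individual paths are drawn from exactly the same
transition rows as the cohort engine (categorical draws per cycle,
vectorised over individuals), so the cohort engine serves as the oracle
for its mean outcomes.

## Synthetic data

The survey generator implements the textbook selection mechanism:
employment from a probit index, log earnings from a linear index, errors
bivariate with correlation ρ (default 0.5, earnings scale 0.6), exclusion
variables independent of everything else. Item severities rise mildly
with age. Earnings are lognormal by construction. The patient generator
draws ages near 60 (SD 10.94, clipped 40–90), baseline items
binomial(4, 0.54) per item — calibrating the limitations index mean to
~54/100 — and follow-up items as baseline minus a Poisson improvement
(mean 1.5 severity points per item), floored at zero. The life-table
generator uses a Gompertz hazard a·e^{bx} per gender (a = 4.0e-5/2.2e-5,
b = 0.085/0.088 for men/women), giving life expectancy at 60 in the low
20s, with q forced to 1 at age 110.

What the synthetic data do **not** emulate: survey weights and complex
survey design, occupational heterogeneity, item-level measurement error
or recall bias in the retrospective baseline, real registry age-gradients
in revision risk, and period-to-cohort life-table effects. Passing tests
therefore demonstrate that the estimators recover known mechanisms of
this form, not that the published point estimates are reproduced —
headline published values depend on restricted microdata and unprinted
tables and are out of desk-scale reach by design.

## Numerical conventions and scale choices

Occupancy mass is conserved to 1e-9 per cycle and verified in tests.
Currency is reported as whole dollars with half-up rounding, full
precision internally; published tables' own rows are off by ±1 from
their column arithmetic, so the profile loader accepts a ±1 discrepancy
in a supplied total column and recomputes the exact component sum.
Problem sizes used by the test suite and acceptance script: synthetic
surveys of n = 5,000 (20 seeds for recovery checks, n = 500 for the
small-sample comparison), patient samples of n = 77 with 1,000 bootstrap
iterations and 100 replications for coverage, 50,000 individuals for the
microsimulation-vs-cohort check, a 10,000-point grid as the bisection
oracle, 2,000 replications of n = 10,000 for ellipse coverage, and 500
PSA draws in the acceptance script. These sizes give Monte-Carlo error
comfortably below the tested tolerances while keeping a full run in the
minutes range.

## Known limitations

- Two-step (not maximum-likelihood) selection estimation; no corrected
  second-stage standard errors.
- Fixture values stand in for unprinted age/gender tables; band-level
  outputs shift if users supply real registry/mortality inputs.
- No crossover from nonoperative care to surgery, by design (the model
  values *access* to surgery).
- No valuation of unpaid work or presenteeism; missed days are the only
  absence channel.
- Single-year cycles without half-cycle correction slightly overweight
  the first year relative to a continuous-time model.
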