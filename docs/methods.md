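# Methods

## The estimation problem

In a prospective population-based pregnancy registry, women enrol at varying
gestational ages (GA) and very early losses may end a pregnancy before the
woman ever enrols. Naive loss proportions are therefore biased by left
truncation: the denominator for an early GA window must contain only women
who were already under observation before the window opened and whose
pregnancy was still ongoing then. `gestloss` implements interval-specific
loss-rate estimation under this observation scheme, a multiple-decrement
projection that converts the interval rates into the expected fate of a
closed hypothetical cohort, and covariate relative-risk models for the two
loss types.

All gestational ages are integer days since the last menstrual period (LMP);
"X weeks Y days" is `7X + Y` days, and the week-labelled window
"a,0–b,6 weeks" is the half-open day interval `[7a, 7(b+1))`. The three
canonical windows are `[42, 56)`, `[56, 84)` and `[84, 140)` days
(6,0–7,6 / 8,0–11,6 / 12,0–19,6 weeks). A spontaneous loss before 140 days
is a miscarriage; an elective termination (MTP) may also occur after 140
days; a delivery at ≥ 140 days with no signs of life is a stillbirth.

## Interval rates with competing-event denominator exclusion

For window `I = [s, e)`, the risk set is

    R(I) = { women : enroll_ga < s  and  no miscarriage/MTP before day s },

including pregnancies with no recorded outcome yet. Women who enrol inside a
window first contribute to the next window (no partial-exposure weighting;
the source analyses work in the same coarse GA bins). Within a window the two
loss types compete, and the estimator for event `E` with competing event `C`
is

    rate_E(I) = 1000 * n_E(I) / ( |R(I)| − n_C(I) ),

i.e. each loss type's denominator excludes the *other* type's same-window
events, so `den_misc + n_MTP = den_MTP + n_misc = |R(I)|`. This is the unique
convention consistent with published tallies of the form 2775 → 307/2663 and
112/2468. Event membership in a window uses the half-open day rule on the
outcome GA. A zero denominator raises an error rather than returning NaN.
Stillbirths/livebirths never count as window losses; validation rejects
deliveries mis-dated before 140 days upstream.

## Cohort projection

Starting from `N0` pregnancies ongoing at 6 weeks (default 1000), each window
removes miscarriages and MTPs simultaneously from the same entering count:

    misc_k = round(N_k * m_k / 1000),   mtp_k = round(N_k * t_k / 1000),
    N_{k+1} = N_k − misc_k − mtp_k,

followed by an absolute post-20-week MTP count, a stillbirth decrement at
`sb/1000`, and a neonatal-death decrement at `nmr/1000` applied to live
births, ending in the count alive at 28 days. The rounding policy is a
parameter: `nearest` (half away from zero, the default, matching
whole-pregnancy tallies), `floor`, or `none` (full precision). Published flow
figures of this kind round each printed cell independently, which no single
consistent policy can reproduce exactly (e.g. a printed 40 where
840 × 48.3/1000 = 40.57); under `nearest` the package's cumulative counts are
713/641/607 against printed 714/642/608 — within one pregnancy at every
stage. In `none` mode the final count satisfies
`N0 · Π_k (1 − (m_k + t_k)/1000) · (1 − sb/1000)(1 − nmr/1000)` exactly
(when the post-20-week MTP count is zero).

## Relative-risk models

Covariates are categorized with conventional cutpoints: maternal age ≤ 20 /
21–25 (ref) / 26–30 / > 30 years; education none / primary (ref) / secondary
/ university+; parity 0 / 1–2 (ref) / > 2; BMI (= weight/height², kg/m²)
< 18.5 / [18.5, 25] (ref) / > 25; first-ANC-visit hemoglobin ≤ 9 / (9, 11] /
> 11 g/dl (ref). The Hb boundary places 9.0 in the severe/moderate band and
the BMI reference band is closed at both ends; both boundaries are
conventions the categorical labels leave open, fixed here once.

For each loss type and window, cases are risk-set members with the event in
the window and comparisons are risk-set members still ongoing at the
window's end; same-window competing-event women belong to neither group
(mirroring the rate denominator). The model is a jointly adjusted log-link
binomial GLM over all five factors with a cluster-level Gaussian random
intercept on the log-risk scale:

    log P(case_ij) = x_ij' β + u_j,   u_j ~ N(0, σ²).

All factors enter one model per event × window (the alternative — one model
per factor — is a plausible reading of adjusted-RR tables; the joint model
is the more common one and is the design adopted here). Exponentiated
coefficients are adjusted RRs with Wald 95% CIs. Complete-case per model:
rows missing any model covariate are dropped.

### Estimation

No installed Python package fits a log-link binomial GLMM, so the marginal
likelihood is maximized directly with a Laplace approximation: rows are first
collapsed to binomial counts per (cluster, covariate pattern); for each
candidate (β, log σ) the scalar cluster modes û_j are found by a vectorized,
damped Newton iteration (the per-cluster objective is strictly concave); the
Laplace-approximate marginal log-likelihood
`Σ_j [ f_j(û_j) − û_j²/2σ² − ½ log(σ² H_j) ]` is maximized over (β, log σ)
with L-BFGS-B (log σ bounded in [log 10⁻³, log 3]); Wald CIs use the inverse
of a finite-difference Hessian at the optimum. Linear predictors are capped
just below zero so fitted risks stay < 1 (the log-binomial parameter-space
boundary); starting values come from the fixed-intercept GLM fit. Fits are
deterministic given data and configuration. With a single cluster the model
falls back to the fixed-intercept GLM with a warning; with a 2×2 table and
no random effect the fit equals the closed-form risk ratio and its log-scale
Wald CI, which the tests verify against hand formulas. Fewer than two cases
or comparisons refuses the fit with a message; |log RR| > 10 is flagged as
possible separation; non-convergence is reported in the result diagnostics,
never silently replaced by a Poisson approximation. No multiplicity
correction is applied.

## Descriptive summaries

Records are grouped as miscarriage / MTP / ongoing at 20 weeks; stillbirths
and livebirths populate the ongoing column (their delivery attendant and
location describe the eventual delivery). MTPs recorded after 140 days sit in
the MTP column by default (configurable, since the convention is genuinely
open). Percentages are reported to one decimal; each block sums to 100 ± 0.2
after rounding. Records with no recorded outcome are reported as a residual
unclassified count, never dropped silently.

## The synthetic registry generator

The generator emulates exactly the features the estimators rely on, with
full ground-truth bookkeeping:

- **Staggered enrollment** over five GA bands (< 6, 6–8, 8–12, 12–20, ≥ 20
  weeks) with default probabilities 0.092/0.289/0.364/0.199/0.056 and a
  uniform day within each band (the earliest band starts at day 28, about
  when a pregnancy becomes detectable).
- **Interval-discrete competing losses.** Configured per-1000 window rates
  (defaults 115.3/101.9/60.3 miscarriage, 45.4/48.3/40.2 MTP) are the
  estimands of the denominator-exclusion estimator; they are converted to
  per-woman categorical probabilities `q_m = a(1−b)/(1−ab)`,
  `q_t = b(1−a)/(1−ab)` so that the estimator is calibrated by construction.
  One categorical draw per woman per window (at most one loss per pregnancy);
  the loss day is uniform within the window. The true within-window hazard
  shape is unknowable from interval tallies, so the generator is
  interval-discrete by design.
- **Covariate effects** multiply the rate-scale targets per
  ``"factor:level"`` (so a configured effect *is* the RR estimand of the
  fitted model); effects pushing any probability to ≥ 1 abort with the
  offending profile named. Women missing hemoglobin carry reference risk.
- **Cluster heterogeneity**: cluster log-risk intercepts ~ N(0, cluster_sd²)
  with default cluster_sd 0.15 (≈ 16% between-cluster rate variation, a
  plausible scale for geographic clusters within one district). The sampled
  frailties are centred to realized mean 1, which calibrates the planted
  rates within each realization while leaving every between-cluster ratio —
  and hence the RR estimands and the cluster-sd scale — unchanged.
- **Left-truncation selection**: a woman whose simulated loss falls on or
  before her simulated enrollment day never enters the registry and is
  re-drawn, reproducing the fact that very early losses may never enrol.
- **Perinatal stage** for 140-day survivors: post-20-week MTP (default
  3.1/1000, matching ~2 such events per ~642 survivors), stillbirth
  (26/1000), livebirth with a 28-day neonatal death draw (24/1000).
- **Missingness**: 2.2% of records have enrollment GA blanked (driving the
  ~97.8% analysis-retention funnel); 3% missing hemoglobin.
- **Covariate marginals and care descriptors** (age bands 0.25/0.45/0.22/
  0.08; education 0.15/0.25/0.50/0.10; parity 0.35/0.35/0.20/0.07/0.03; BMI
  ~ N(20.5, 3²) with height ~ N(1.56, 0.06²); Hb ~ N(10.8, 1.5²); ANC-visit
  bands, delivery attendant and location drawn per outcome group with
  probabilities matching a rural South-Asian registry's published
  descriptive table) are plausible fixed choices — no registry publishes its
  full joint distribution, and nothing downstream depends on them beyond the
  categories' being populated.

Identical (config, seed) reproduces a byte-identical registry.
`truth_rate` recomputes each window rate from the planted values through an
independent code path with the same risk-set and denominator conventions and
must agree with the record-level estimator exactly.

### What passing synthetic tests does and does not show

The generator realizes the estimator's own sampling assumptions
(interval-discrete hazards, one loss per pregnancy, enrollment independent
of future risk given covariates and cluster, non-informative GA
missingness). Recovery on synthetic data therefore validates the
estimators' correctness under those assumptions; it cannot validate them
against real-world features the generator omits — gestational dating error,
multiple gestation, within-window hazard shape, informative enrollment or
loss under-reporting.

## Problem sizes and numerical tolerances in the test suite

Published-tally checks run on a reconstructed registry of ~32,400 records
and are exact to the printed decimal. Estimator-recovery checks use one
default-condition registry of n = 30,000 (each window rate within 3 binomial
SEs of its target). Generator-calibration t-tests (α = 0.01) use 50 seeds at
n = 20,000. RR-model null coverage uses 200 replicates at n = 20,000 with 20
clusters, fitting the window with the most cases (8,0–11,6-week miscarriage)
per replicate and pooling all non-reference Wald CIs; the assertion band
0.93–0.97 allows binomial noise across replicates plus Wald/Laplace
approximation slack. Effect recovery plants an MTP RR of 2.19 for age > 30
and requires the mean 12,0–19,6-week estimate over 50 seeds within 2
simulation SEs of truth. Closed-form equivalences (2×2 risk ratio, survival
products in continuous mode) are asserted at 10⁻⁶ relative or tighter.

## Known limitations

- The mixed-model CIs are Wald intervals on a Laplace-approximate
  likelihood: adequate at registry scale, not exact in tiny samples or with
  very few clusters.
- The log-binomial parameter-space boundary is handled by capping, not
  constrained optimization; data pushing fitted risks near 1 may converge
  poorly (reported in diagnostics).
- No continuous-time survival machinery (Kaplan–Meier, cumulative-incidence
  competing risks): the analysis is deliberately confined to coarse GA bins.
- No uncertainty propagation onto projected cohort counts; the projection
  reports point counts only.
- Twin/multiple gestations are a single record with one recorded outcome;
  denominator handling of multiples is out of scope.
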