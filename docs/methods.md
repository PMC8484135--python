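# Methods

`popkin` implements a population-pharmacokinetic analysis of an IV-infused
therapeutic antibody in patients with gastric/gastroesophageal
adenocarcinoma: a two-compartment disposition model with parallel linear and
Michaelis–Menten elimination, log-normal interindividual variability (IIV),
a log-scale additive residual model, FOCE-class maximum-likelihood
estimation, stepwise covariate modelling, simulation-based qualification
(pcVPC, NPC, bootstrap) and steady-state exposure simulation. Because no
patient-level data are deposited, a synthetic-trial generator reproduces the
statistical structure of the study dataset so that every stage of the
pipeline can be exercised and checked end to end.

## Structural model

States are amounts in the central (`Ac`, mg) and peripheral (`Ap`, mg)
compartments; serum concentration is `C = Ac/Vc` in µg/mL (≡ mg/L):

    dAc/dt = −[ (Vmax/(Km + C))/Vc · 10⁻³ + CL/Vc + Q/Vc ]·Ac + (Q/Vp)·Ap + R(t)
    dAp/dt = (Q/Vc)·Ac − (Q/Vp)·Ap

with `CL` linear clearance (L/day), `Vc`/`Vp` central/peripheral volumes
(L), `Q` inter-compartmental clearance (L/day), `Vmax` (µg/day) and `Km`
(µg/mL) the saturable (target-mediated) pathway, and `R(t)` the infusion
rate (mg/day; the 10⁻³ converts the µg-scale `Vmax` into mg/day). Time is in
days throughout; tabulations that estimate rate parameters per hour relate
by a factor 24 (e.g. ln 0.311 = −4.35 + ln 24 for the clearance intercept).

Infusions are integrated piecewise between event boundaries with a constant
input term — no bolus approximation, because 30-minute infusions materially
shape the peak. The ODE route uses LSODA at rtol 1e-8 / atol 1e-10. With
`Vmax = 0` the system is linear and the package uses the closed-form
bi-exponential solution (hybrid rate constants α, β from the 2×2 disposition
matrix), fully vectorized across subjects, doses and times; the two routes
agree to 1e-6 relative and the closed form is additionally verified against
an independent matrix-exponential oracle in the tests.

At the fitted parameters the saturable pathway is numerically negligible:
its maximal clearance `Vmax/Km` ≈ 0.63 mL/day versus `CL` = 311 mL/day
(< 0.3% at any concentration, < 0.01% at therapeutic concentrations). The
estimation engine and the large simulation loops therefore run on the linear
fast path; the generator's default integrates the full system. `Vmax` is
implemented exactly as tabulated (µg/day); a different unit scaling, if ever
needed, is a one-line change of the conversion constant.

The terminal half-life is ln 2 over the smaller hybrid rate constant; in the
degenerate `Q → 0` geometry that eigenvalue carries vanishing amplitude in
serum, so the implementation falls back to the slowest *observable* phase.

## Population model

Individual parameters are log-normal:
`P_i = exp(θ_P + Σ_e k_e·x_e,i + η_P,i)`, with continuous covariates
entering as power functions of `Cov/Cov_ref` and categorical covariates as
`exp(k)` for the non-reference level. The final covariate model is weight
(ref 64 kg) and albumin (ref 38 g/L) on CL, combination therapy on CL
(k = −0.200), weight on Vc, and female sex on Vc (k = −0.164); typical
values CL 0.311 L/day, Vc 3.58 L, Q 0.952 L/day, Vp 2.71 L, Vmax 2.80
µg/day, Km 4.45 µg/mL. IIV is carried on Vmax, CL, Vc and Vp with one
off-diagonal Ω element (CL–Vc covariance 0.0128); the residual model is
additive on the log scale (σ = 0.146). IIV is reported as CV% = 100·ω (the
convention that reproduces the tabulated 29.2/14.9/60.4%); the log-normal
convention 100·√(exp(ω²)−1) is available as an option. Missing continuous
covariates are imputed at the reference (population median) and missing
categoricals at the reference level, with a logged warning.

## Estimation

The marginal likelihood is approximated FOCE-style. For each subject the
conditional mode η̂ (the EBE) solves a penalized nonlinear least-squares
problem, found by a vectorized damped Gauss–Newton across all subjects at
once (finite-difference sensitivities, step 1e-4; per-subject step halving).
Linearizing the log-prediction about η̂ gives the per-subject marginal
Gaussian with covariance `G Ω Gᵀ + σ² I`; the OFV is −2× the summed
log-density, additive constants included, so ΔOFV between nested models is
χ²-comparable. Because the residual SD is constant on the log scale, the
residual variance does not depend on η and the FOCEI interaction term is
exact for this error model. Exact numerical equivalence with any particular
commercial implementation is not a goal; correctness is demonstrated by
parameter recovery on synthetic data at the study design.

The outer problem (θ, covariate coefficients, the Cholesky factor of Ω with
log-parameterized diagonal, log σ) is solved by a box-bounded BFGS written
for this surface: steps are clipped to 0.3 per (log-scale) coordinate so the
search cannot jump into the cliff regions where predictions collapse,
Armijo backtracking accepts simple decrease, the inverse-Hessian estimate is
Shanno-scaled after the first curvature update, and the inner warm start is
committed only at accepted iterates so that the objective is deterministic
within each finite-difference cycle (warm-start drift between evaluations
otherwise turns the gradient into noise — this failure mode was observed and
is the reason for the design). Convergence is declared after two consecutive
relative OFV changes below 1e-6. Gradients are forward differences with
step 1e-4. Starting values for synthetic-data fits are the generative values
perturbed ×1.5.

CWRES are the per-subject residual vectors `y − f(η̂) + Gη̂` whitened by the
Cholesky factor of the linearized marginal covariance; on self-simulated
data they are approximately standard normal. The whitening couples
observations within a subject, so a gross outlier can drag same-subject
neighbours over a threshold — the outlier-refit loop (drop |CWRES| > 5,
refit once) therefore reports the excluded rows explicitly. Shrinkage uses
η-shrinkage = 1 − SD(EBE)/ω and ε-shrinkage = 1 − SD(IWRES). Standard
errors, when wanted, come from the nonparametric bootstrap rather than a
covariance step.

`Vmax`, `Km` and the `Vmax` IIV are fixed (not estimated) in the default fit
configuration: virtually all study dosing is in the linear range, so the
data carry almost no information about them — consistent with the very
large IIV and shrinkage reported for `Vmax`.

## Covariate search

Screening regresses each EBE on `ln(cov/median)` (continuous; matching the
power form the covariate would take in the model) or runs a one-way ANOVA
(categorical) at p < 0.05, with a warning if η-shrinkage exceeds 30%.
Forward inclusion refits each remaining candidate and accepts the largest
ΔOFV among those with p < 0.01 (χ², df = parameters added); ties break
toward fewer parameters, then name. Backward elimination removes the effect
whose deletion costs the least, while the cost is below 10.83 (p < 0.001,
1 df). The dedicated body-weight step tests weight on all four disposition
parameters jointly (4 df) and then prunes it from Q and Vp if the joint
removal is non-significant at p < 0.01 (2 df, threshold 9.21). Candidates
are screened once, not re-screened after each inclusion.

## Diagnostics

pcVPC: observations and simulated replicates are corrected by
`y · median(PRED in bin)/PRED`, where PRED is the population prediction
(η = 0) with each subject's own covariates and doses; bins default to
quantile bins on time with ≥ 8 observations per bin; the simulated 95% CI of
each percentile is the 2.5th–97.5th percentile of the replicate-level
percentiles (1000 replicates by default). NPC reports observed vs nominal
outside-fractions for 50/90/95% prediction intervals with a replicate-based
reference range. The bootstrap resamples subjects with replacement
(optionally stratified, e.g. by therapy), refits each replicate starting
from the point estimates, and reports medians with percentile CIs; more than
20% failed replicates flags the result unreliable.

## Exposure simulation

The target regimen is 15 mg/kg every two weeks for 52 weeks plus one
7.5 mg/kg dose on cycle 1 day 8; steady state is operationalized as the last
14-day interval of that regimen (not an analytic steady-state assertion).
AUCss is a trapezoid integral on a dense grid (≥ 240 points per interval);
Cmax,ss is the maximum and Ctrough,ss the value at the interval end.
Tornado scenarios simulate typical individuals (η = 0) at the 10th/90th
population percentiles of weight (45/79 kg) and albumin (30/44 g/L) and the
non-reference categorical levels; weight scenarios re-scale the mg/kg dose
as well as the parameters, which is why lighter patients have *lower*
exposure despite their smaller clearance. Population simulations draw η from
Ω (or accept externally supplied per-subject η, mimicking an EBE-based
simulation) and summarize geometric means with 5th/95th percentiles overall
and by subgroup; renal- and hepatic-function class boundaries are
configuration data, not code constants.

## Synthetic data

The generator emulates the pooled three-trial dataset: 173 patients (85
monotherapy across a 0.3–15 mg/kg dose escalation, 88 combination therapy at
15 mg/kg + 7.5 mg/kg day 8), weight from a truncated log-normal (median
63.9 kg, range 35.5–148), albumin truncated normal (median 38 g/L, range
19–50.2), other laboratory covariates as truncated log-normals around the
published medians (right-skew typical of labs), and categorical frequencies
as published (65.3% male, 50.9% combination therapy, ...). The sampling
schedule — cycle-1 rich sampling (end of infusion, 4 h, days 1, 2, 7) plus
pre-dose troughs at cycles 2, 3, 5 and 9 — is an explicit assumption (the
exact clinical schedule is not published) chosen to give 9 samples/subject,
i.e. 1557 scheduled observations against the study's 1552. Nineteen
below-LLOQ observations (1.22%) are planted at the late troughs of the
lowest-dose subjects and are removed by the censor-and-drop LLOQ rule
(0.125 µg/mL, strict inequality), mirroring the study's BLQ accounting;
planted-outlier options support the outlier-refit tests. Covariates are
generated independently by default, with an optional knob coupling weight
and sex for screening tests that need confounding.

What the generator does not emulate: dropout, dose modifications,
time-varying covariates, assay batch effects, enrollment structure, or the
real joint covariate distribution. Passing recovery/calibration tests on
these data therefore demonstrates the correctness and internal consistency
of the procedures at the study's size and design — not the reproduction of
the real-data estimates, bootstrap intervals or EBE-based exposure summaries,
which require the unavailable patient-level data.

## Problem sizes used in the test suite

Checks are sized to what they measure: exact arithmetic is tested directly;
study-scale claims (parameter recovery, covariate-search recovery, CWRES /
pcVPC / NPC calibration) run at the full 173-subject design, with 20
replicates for recovery bias and 5 for search recovery; the χ²(1)
calibration of ΔOFV for a null covariate uses 100 replicates of a reduced
30-subject, 4-sample design with IIV on CL only (the statistic's null
distribution does not depend on the study's full size); bootstrap behaviour
is demonstrated at 12 replicates on 40 subjects. pcVPC/NPC use 300 simulated
replicates in tests; the production default stays 1000.

## Known limitations

- Only the linear-disposition path is available inside the estimation
  engine; models whose saturable pathway matters at the observed
  concentrations would need the ODE route wired into the objective.
- BLQ data are censor-and-dropped; no likelihood-based (M3-type) BLQ
  handling.
- No inter-occasion variability, no combined additive+proportional residual
  on the natural scale, no SAEM/importance-sampling estimators.
- The bootstrap is the only uncertainty quantification; there is no
  sandwich/covariance step.
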