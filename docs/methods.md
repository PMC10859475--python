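# Methods

`tigepk` re-implements a population-pharmacokinetic (PPK) analysis of
tigecycline in critically ill adults as a reusable, tested pipeline. This
note documents the models, the numerical choices, and what the synthetic
validation experiments do and do not demonstrate.

## Structural model

Disposition follows a two-compartment model with first-order elimination,
parameterized as clearance CL (L/h), central volume V1 (L),
intercompartmental clearance Q (L/h) and peripheral volume V2 (L).
Dosing is a zero-order intravenous infusion (default 30 min). The central
concentration for one infusion is the standard biexponential solution

    C(t) = (R0/V1) [ A/α (1 − e^{−α t'}) e^{−α t''} + B/β (1 − e^{−β t'}) e^{−β t''} ]

with t' the elapsed infusion time, t'' the time since the end of infusion,
A = (α − k21)/(α − β), B = (k21 − β)/(α − β), and α, β the roots of
s² − (k10 + k12 + k21)s + k10·k21 (k10 = CL/V1, k12 = Q/V1, k21 = Q/V2).
Multiple doses superpose linearly. The closed form is validated against
adaptive-step numerical integration of the compartment ODEs to relative
error < 1e−6 over random parameter draws.

The degenerate root case α ≈ β (relative gap < 1e−10) raises an error
rather than switching to the repeated-root form: it cannot arise for any
plausible parameter set of this drug, so silently continuing would mask an
upstream problem.

Steady state is realized by explicit superposition of prior doses
(default ≥ 20; the study itself samples at the 7th dose, which is supported
exactly). At the half-lives implied by the published parameters
(β ≈ 0.04 h⁻¹), 20 doses leave the residual accumulation error below 0.1%.
The analytic identity AUC₀₋₂₄ = daily dose / CL is also implemented and is
the default route for simulation work; the trapezoid pipeline (0.05 h grid,
linear-up/linear-down) agrees with it to < 0.5% and serves as a cross-check.

## Covariate model

Continuous covariate–parameter relations come in linear, exponential and
power families, each normalized by a stored population median; categorical
covariates use a power-of-indicator form. The published final model is

    CL (L/h) = 3.09 + (CCr/77) × 3.28
    V1 (L)   = 32.1 × (BW/61)^1.95
    Q (L/h)  = 39.7 × (log GGT/1.7)^0.956 × (log TBIL/1.2)^−0.912
    V2 (L)   = 113  × (BW/61)^1.61 × (log ALB/1.4)^4.52

The "log" in the liver-function terms is base-10: the normalization
constants 1.7, 1.2 and 1.4 equal log10 of the reported median GGT
(53 U/L), TBIL (15.7 μmol/L) and ALB (27.9 g/L); natural logarithms do
not reproduce them. The base is configurable but defaults to 10.
Normalization constants are stored with the model rather than recomputed
from data, so simulating from the published model is bit-reproducible.

Creatinine clearance uses Cockcroft–Gault with serum creatinine reported in
μmol/L and converted internally to mg/dL (÷ 88.4); females get the 0.85
factor. Ages that would make the formula non-positive floor the result at a
configurable minimum (1 mL/min) with a warning.

Interindividual variability (IIV) is exponential, parameter = typical ×
exp(η), η ~ N(0, ω²). ω and the proportional residual σ are reported as
100·√variance (approximate %CV), matching the published table
(ω_CL 27.0%, ω_V1 72.5%, ω_Q 18.8%, none estimable on V2; σ 2.02%).

## Estimation

The marginal likelihood is approximated by a Laplace expansion at each
subject's conditional η mode with two FOCE-I-style conventions: the
residual variance is evaluated at the individual predictions
("interaction"), and the curvature entering both the Newton mode search and
the Laplace log-determinant is the Gauss–Newton linearization
2 JᵀWJ + 2Ω⁻¹ (J = ∂f/∂η, W = 1/var). This is the closest
re-implementable analogue of FOCE-I; exact numerical agreement with
NONMEM's implementation is not claimed, and all published-value comparisons
are made through simulation–reestimation rather than objective-function
equality. In the Ω → 0 limit the objective reduces exactly to the
fixed-effects −2 log-likelihood, and on small problems it matches
brute-force adaptive quadrature of the marginal likelihood to within 2
objective-function units (tested).

Numerics: positive parameters (typical values, ω, σ) are log-transformed;
covariate-effect coefficients are unconstrained. The outer problem is
solved by L-BFGS-B with forward-difference gradients (step 1e−5 in
transformed space, ftol 1e−8, projected-gradient tolerance 1e−4); the inner
η modes use damped Newton with a central-difference Jacobian (h = 1e−5),
gradient tolerance 1e−7, warm-started across outer iterations. The inner
tolerance is deliberately no tighter: the mode-objective error is quadratic
in the gradient norm (≈1e−12 at 1e−7), while tighter settings make the
finite-difference Newton dither without changing any estimate. Predictions
are floored at 1e−10 mg/L so the proportional error model cannot produce a
degenerate likelihood. Optimizer failure returns a non-converged result
with diagnostics, never a silent answer.

Standard errors use the BHHH (cross-product-of-scores) information with
per-subject scores from central differences of the subject-level objective
contributions, which is positive-semidefinite by construction; a
finite-difference Hessian of the marginal objective was numerically
indefinite at feasible step sizes and is not used. AIC = OFV + 2p.

## Covariate selection

Forward inclusion adds, at each step, the candidate with the largest OFV
decrease among those with a decrease ≥ 3.84 (χ²₁, p < 0.05); backward
elimination retains an effect only if its removal raises the OFV by
strictly more than 10.83 (p < 0.001). Boundary semantics follow the
published wording exactly ("a decrease of 3.84" is inclusive; retention
requires an increase *greater than* 10.83). Ties go to the larger change,
residual ties to candidate order; every tested change is logged, and a
candidate whose fit fails is skipped and logged rather than aborting the
search. A Spearman pre-screen (|ρ| > 0.5 by default, configurable — the
original analysis names the step but not the statistic or cutoff) flags
covariate pairs that should not co-enter the candidate set.

## Diagnostics

PRED is the population prediction (η = 0), IPRED the prediction at the
empirical Bayes η, and CWRES the FOCE-linearized residual decorrelated by
the Cholesky factor of J Ω Jᵀ + diag(σ²·IPRED²), using the marginal mean
approximation f(η̂) − J η̂. Under a correctly specified model CWRES is
approximately standard normal; on the full synthetic design (98 × 8
observations) its sample mean lies within ±0.1 and its SD within
[0.8, 1.2] (tested).

The bootstrap resamples whole subjects with replacement at the original
cohort size, refits, and reports per-parameter medians and 2.5/97.5
percentiles; failed refits are excluded and counted, and the summary is
flagged unreliable above 20% failures. No stratification is applied.

The VPC simulates replicate datasets under the original design (same
subjects, doses, times, covariates), computes the 5th/50th/95th
concentration percentiles per time bin and per replicate, and reports the
2.5–97.5 envelope of each percentile across replicates. Bins default to
the eight nominal sampling times of the intensive design (pre-dose, 0.5,
1, 2, 3, 4, 6, 12 h after dose), assigned by nearest nominal time after
dose; custom bin grids are supported for other designs. Percentiles are
computed on the raw concentration scale; plotting is conventionally on a
log axis. Prediction correction is not implemented.

## Monte Carlo PTA and dose optimization

Virtual patients are drawn at stratum covariates (one axis varied — CCr at
30/80/130 mL/min, body weight at 40/60/80/100 kg, or liver function
normal/abnormal — others pinned at the model's normalization medians),
individualized with the published ω's, and scored on steady-state
AUC₀₋₂₄/MIC against indication-specific targets (6.96 for cIAI, 12.8 for
CAP, 17.9 for cSSSI) over MIC 0.125–8 mg/L for 50 and 100 mg q12h
regimens, 1,000 virtual patients per group by default. A regimen is
recommended when PTA ≥ 90%.

Because the model is linear, AUC₀₋₂₄ at steady state equals daily dose
divided by individual CL; the trapezoid route is retained as a cross-check.
Two consequences are exploited as tests: PTA has a closed form when only
ω_CL is active (PTA = Φ(ln[daily dose/(MIC·ratio·CL_typ)]/ω_CL)), and the
liver-function strata cannot change PTA (GGT/TBIL enter only Q, which
cancels from the steady-state AUC) — the Monte Carlo grid reproduces both.

AUC₀₋₂₄ (not AUC over one 12-h interval) is used for the AUC/MIC index, the
standard convention for this drug; at steady state the two differ exactly
by the factor 24/τ and both are exposed. The liver-abnormal stratum uses
TBIL > 2× and GGT > 3× their upper limits of normal, with ULN defaults
21 μmol/L and 60 U/L (not stated in the source; configurable). Body-weight
strata are decoupled from renal function by default so each axis isolates
one covariate; an optional coupled mode feeds the stratum weight through
Cockcroft–Gault instead.

Per-cell cohorts are seeded by spawning from a master seed keyed on the
cell coordinates, so the grid is reproducible and cells are independent; a
common-random-number mode shares the cohort within a stratum across
regimens so dose-monotonicity holds exactly in tests.

## Synthetic cohort generator

The generator emulates the study design: 98 subjects, q12h 30-min
infusions, 92.9% on 100 mg/day and the rest on 200 mg/day, loading dose
double the maintenance dose (on by default, configurable off since the
source does not state whether every subject received one), eight samples
per subject at the 7th-dose interval (pre-dose and 0.5–12 h post-dose).
Age, body weight and BMI are truncated normal from the reported mean ± SD
and range; laboratory covariates are lognormal matched to the reported
median and IQR (μ = ln median, σ from the IQR via normal quantiles — the
source reports no distributional forms, and lognormal is the natural
choice for positive skewed labs) and truncated to the reported min–max by
rejection. Sex is Bernoulli (66.3% male); CCr is derived per subject by
Cockcroft–Gault. Covariates are static per subject (measured once in the
study). Concentrations come from the published final model with
proportional error; ε draws with 1 + ε ≤ 0 are rejected and redrawn
(negligible at σ ≈ 2%). 98 × 8 = 784 records are generated by default; a
completely-at-random dropout of 33 records reproduces the 751 the study
analysed (which records were missing is not reported, so
missing-completely-at-random is assumed).

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: assay error beyond a proportional term,
time-varying organ function, ECMO or renal-replacement subpopulations,
nonlinear plasma protein binding (a known property of this drug, excluded
from scope), correlated random effects, and model misspecification of any
kind. Simulation–reestimation demonstrates that the estimator recovers the
model that generated the data at the study's design; it cannot demonstrate
that the published model is correct for real patients.

## Validation experiments and problem sizes

- Simulation–reestimation: 5 replicate cohorts (98 subjects × 8 samples,
  seeds 1–5), final model refit to each; medians of the recovered
  parameters compared to the generating values (structural within 15%,
  covariate effects within 25%, ω_CL and σ within 30%). A single fit takes
  well under a minute on one CPU.
- Selection power: 40-subject cohorts with one true effect (BW on V1,
  power 1.95, ω_V1 40%) and one null candidate, 20 replicates. The design
  was sized by a likelihood-ratio power calculation: the backward
  threshold of 10.83 requires a noncentrality near 25 for reliable (>95%)
  retention of a true effect, which 40 subjects provide; 30 do not.
- Bootstrap/VPC tests run scaled down (handfuls of resamples on 8-subject
  cohorts; hundreds of VPC replicates), checking reproducibility, ordering
  invariants, envelope collapse at zero variance and self-coverage, not
  production summaries. Production defaults remain 1,000 resamples and
  1,000 replicates.
- PTA grids in tests use 2,000–10,000 virtual patients per cell where a
  tolerance demands it; the production default is 1,000 per group.

## Known limitations

- The estimator is a Laplace/FOCE-I analogue, not a NONMEM clone; its OFV
  scale is internally consistent but not comparable to published OFVs.
- Off-diagonal Ω, interoccasion variability, SAEM-type estimators and
  η-shrinkage reporting are out of scope.
- The published real-data quantities that depend on the original
  concentrations (AIC values, the covariate-screening ΔOFV of 38.968) are
  not reproducible without the study data and are not targeted.
- PTA uses total-drug AUC; fAUC/MIC with nonlinear protein binding is
  explicitly out of scope.
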