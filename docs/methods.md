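# Methods

This note documents the models, algorithms, defaults and numerical
choices implemented in `foalpk`, and what the synthetic-data-based tests
do and do not demonstrate.

## Structural and statistical model

Disposition is a linear mammillary model with IV bolus input and
first-order elimination.  The 1- and 2-compartment cases use the closed
bi-exponential form: with micro-constants `k10 = Cl/V1`, `k12 = Q/V1`,
`k21 = Q/V2`, the hybrid rate constants α ≥ β are the roots of
`s² − (k10+k12+k21)s + k10·k21`, computed as
`α = (s + √(s²−4p))/2`, `β = p/α` to avoid cancellation.  A unit bolus
gives `C(t) = A·e^{−αt} + B·e^{−βt}` with `A = (α−k21)/(V1(α−β))`,
`B = (k21−β)/(V1(α−β))`; multi-dose profiles are exact superpositions.
When `|α−β|/α < 1e−10` the repeated-root form
`C(t) = e^{−λt}(1+(k21−λ)t)/V1` is used.  The 3-compartment candidate
(needed only for structural model comparison) goes through the
eigendecomposition of the rate matrix rather than hand-coded
coefficients.  Time is hours, the first dose defines t = 0, doses are mg
of ampicillin base, and the bolus is instantaneous.

Between-subject variability is log-normal and diagonal.  Covariates enter
log-linearly as powers of `cov/reference`; the final model carries age on
Cl and V2 with the centering constant 61.8 h (the weighted mean age of
the cohort; the printed footnote's "years" is read as a typo for hours,
since every age in the analysis is in hours).  The covariate machinery is
generic — any positive covariate on any parameter — so the
tested-but-rejected weight/albumin/creatinine candidates can be screened,
but only the two age terms ship in `reference_model()`.

Residual error supports constant, proportional, combined1
(`sd = a + b·C`) and combined2 (`sd = √(a²+b²C²)`) forms; combined1 is
the final model.  A defensive floor of 1e−10 mg/L keeps the SD positive.
Observations below the LLOQ (0.3 mg/L) are interval-censored on
[0, LLOQ] — two-sided, not left-censoring at the LLOQ — and contribute
`log[Φ((LLOQ−C)/sd) − Φ((0−C)/sd)]`.

## SAEM estimation

`saem_fit` maximises the marginal likelihood by stochastic approximation
EM.  Per iteration and chain, each subject's η vector is updated by
Metropolis-within-Gibbs: two component-wise random-walk passes plus one
joint random-walk kernel, with proposal scales initialised at 0.8 ω and
adapted toward 35% acceptance during the exploratory phase only (frozen
afterwards so the smoothing phase is a fixed-kernel chain).  Censored
observations enter the η update through the interval probability; for
the residual-error update the latent concentration is additionally
sampled from the truncated Normal on [0, LLOQ] so that complete-data
statistics apply.

Defaults: 2 chains, 300 exploratory iterations (step size 1), 150
smoothing iterations with step size `1/k^0.7`.  The M-step solves, per
parameter, a linear regression of the sampled log-individual values on
the covariate design (fixed coefficients held by constrained least
squares), with ω² from the stochastically averaged residual variance;
the error constants are re-estimated each iteration by damped Newton
(combined1), closed forms (constant/proportional) or Nelder–Mead
(combined2) and blended by the same step-size schedule.

Stabilisers, chosen for robustness on weakly identified fits (the reason
the original analysis fixed V2_pop and ω_Q): during the exploratory phase
variance-type parameters (ω, a, b) may shrink by at most 5% per
iteration (simulated annealing) and grow by at most 15%; ω is capped at
4 (a log-scale SD of 4 is far beyond physiological BSV), the additive
error at twice the data SD, the proportional error at 5; exponentials of
linear predictors are clipped at e^±30.  None of these bounds is active
in a healthy fit.

Any parameter can be frozen (`fixed`/`omega_fixed`); frozen parameters
are excluded from the information matrix and from BICc penalty counts.
Parameters without BSV are not estimable by this sampler — fix a small ω
instead; this is validated at spec construction.

Convergence is flagged, not silently accepted: the relative drift of each
free parameter between the first and last thirds of the smoothing phase
(scale `max(|estimate|, 0.1)`) must stay below 0.25, and collapsing
omegas (< 0.01) are warned about.  The criterion is deliberately strict;
in bootstrap studies 60–70% of short-schedule replicates pass it, and
summaries use converged replicates only.

## Uncertainty, likelihood, model comparison

Standard errors come from the outer product of per-subject score vectors
(Fisher/Louis identity: the marginal score is the conditional expectation
of the complete-data score, averaged over conditional-distribution
samples), on the transformed scale — log for positive parameters,
identity for covariate coefficients — with delta-method mapping back, so
RSE% of a log-parameter equals 100·SE(log).  With 12 subjects this OPG
estimator is conservative; reported RSEs on synthetic cohorts run wider
than the study's stochastic-approximation values.

The marginal log-likelihood uses importance sampling (default 10 000
draws) around each subject's conditional distribution: a Normal proposal
centred at the conditional mean with 1.3× the conditional SD, floored at
0.3 ω so the weights stay bounded even when a conditional chain barely
moves; the Monte Carlo SE is reported.  Model selection uses a corrected
BIC with a hybrid penalty — `log(N_subjects)` for fixed effects, betas
and omegas, `log(N_obs)` for residual-error constants.  The exact penalty
convention of the original software is not published, so BICc values are
meaningful for Δ comparisons within this package only.

Covariate screening follows the one-at-a-time loop with all four
retention criteria logged: BICc drop, BSV drop, Wald p < .05 (two-sided,
`z = β/SE`, SE optionally given as RSE%), and a parametric-bootstrap CI
excluding zero.

Empirical Bayes machinery returns conditional-mode (Nelder–Mead on the
conditional log-density) and conditional-mean etas plus MCMC samples;
shrinkage is `1 − sd(η)/ω` on the pooled conditional samples.

## Diagnostics

The pcVPC uses the Uppsala prediction correction (observation ×
bin-median population prediction / own population prediction), 8
quantile bins (sparse bins merged with a neighbour) on absolute time or
time-after-dose, 10th/50th/90th observed percentiles against 90%
prediction intervals from (default) 1000 simulated replicates, per-bin
outlier flags, and the fraction of observations inside the pooled 90%
band.  Censored observations are plotted at the LLOQ but excluded from
observed percentiles.  Note that prediction correction absorbs part of a
global misfit, so the percentile-outlier flags are a sharper
misspecification signal than raw coverage.

NPDE decorrelates each subject's observation vector with the
simulation-based mean and Cholesky factor of the covariance, maps ranks
through the inverse Normal (`(r+0.5)/(K+1)` to avoid ±∞), and reports
Shapiro–Wilk and sign-test (symmetry about zero — the specific symmetry
test used originally is not named) p-values; censored rows are excluded
and flagged.  IWRES are residuals standardised by the error SD at the
conditional-mean individual predictions.

The parametric bootstrap (SSE) re-simulates the fixed study design —
same subjects, covariates, dose events and sampling times, censoring
applied on [0, LLOQ] — refits each replicate by SAEM (initialised at the
generating values, per standard SSE practice), and reports medians,
2.5–97.5% CIs and bias `(mean−reference)/reference·100` over converged
replicates, plus the convergence rate.

## PTA simulation

One virtual subject = one draw of (population parameters under
uncertainty, covariates, etas).  Parameter uncertainty is log-normal for
positive parameters and Normal for betas with SDs from the reported
RSEs, independent across parameters: the estimate covariance matrix is
not published, and this independence is the main reason the simulated
old-population PTAs run ~2–4 points below the printed ≥90% claims while
the no-uncertainty engine reproduces them — a documented limitation, not
a tuning knob.  Omegas and error constants carry uncertainty too
(the original simulations carried uncertainty "in random and fixed
effects").

Covariates: the study scenario resamples (age, weight) rows with
replacement from a study-like cohort table; age scenarios draw log-normal
ages (e.g. median 10 h or 120 h, log-SD 0.5) with weights resampled
independently — the joint age-weight distribution is not published, and
independence ignores that older foals are heavier.  Dose = mg/kg ×
weight; parameters are absolute (L, L/h), so weight acts only through
the dose.

fT>MIC is evaluated on the noise-free individual predicted free profile
(fu = 0.85) over the full 0–48 h window on a 0.05 h grid with
log-linear crossing interpolation (exact for mono-exponential segments);
a root-bracketing path on the exact piecewise bi-exponential is
available and agrees to <1e−3.  Residual error is not added to
concentrations for target evaluation (standard practice; a flag exists
for sensitivity analyses).  A threshold ≤ 0 returns fraction 1 by
convention.  The MIC grid is the doubling series 0.016–4 mg/L; regimen
recommendations pick the least-intensive optimal regimen ordered by
daily dose then frequency, with an explicit "switch antimicrobial" flag
when the grid is exhausted.

## Synthetic cohort generator

The generator emulates the study design from published summaries only:
ages from a monotone log-linear interpolation of the printed quantile
summary (min 9, Q1 19.7, median 78, Q3 180, max 194.5 h) — chosen over
any parametric family because the printed IQR nearly spans the range and
a log-uniform or log-normal law cannot match both the median and the
IQR; weight and creatinine log-normal and albumin Normal matched to the
printed median/IQR; per-foal sampling schedules with dense early
sampling (0.25–4 h) plus post-dose peak / pre-dose trough pairs, counts
drawn to a median of 13 (range 12–24); 20 mg/kg q6h dosing resolved to
absolute mg at each foal's weight; censoring at 0.3 mg/L.  An optional
flag reproduces the one extreme-creatinine foal (63.8 mg/L, the
youngest) for covariate-robustness experiments.

What passing tests on these cohorts show: the estimation, diagnostic and
simulation machinery is internally calibrated under the published design
and model.  What they do not show: recovery of the published point
estimates from the real observations (not public), correctness of the
age-weight independence assumption, or behaviour under model
misspecification beyond the perturbations tested.

## Problem sizes and tolerances used in validation

PTA checks use 1000 virtual subjects per claim.  The bootstrap recovery
check uses a 12-foal design with 100 replicates in the acceptance script
and 60 in the test suite, each refit on the default 300+150 SAEM
schedule with reduced conditional-sampling sizes (30 draws after 40
burn-in); the median Cl_pop is compared against the published bootstrap
median within 10% and its 95% CI.  Closed-form profiles match adaptive
ODE integration to 1e−6 relative error over 100 log-uniform parameter
sets; the censored likelihood matches quadrature to 1e−8; the
importance-sampling log-likelihood matches adaptive quadrature on a
1-compartment toy within Monte Carlo error at 40 000 draws.
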