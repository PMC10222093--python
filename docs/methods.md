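# Methods

This note documents the models, conventions and numerical choices behind
`implantpk`, and what the synthetic-data tests do and do not demonstrate.

## Release models

A release model is a closed-form cumulative amount Q(t) (mg) released from
the device by day t, with analytic rate dQ/dt (mg/day). Ten families are
implemented (see the `release_models` module docstring for the full table).
They split into bounded forms with a physical asymptote — first-order,
Weibull, biexponential, second-order — and unbounded power-law/polynomial
forms (zero-order, Higuchi, Korsmeyer–Peppas, Hixson–Crowell before
depletion, Peppas–Sahlin, Population Council). For multi-year implants the
bounded forms are the physically meaningful candidates: an unbounded Q(t)
eventually exceeds any finite load.

Conventions that deserve a word:

* **Second-order.** The family is defined here as the solution of
  dQ/dt = k2·(Qmax − Q)², i.e. Q = Qmax·(1 − 1/(1 + Qmax·k2·t)). The
  alternative sign in the denominator (1 − Qmax·k2·t) is singular at
  t = 1/(Qmax·k2) and negative beyond it, so it cannot describe release;
  the ODE-consistent branch is the only self-consistent choice. A test
  verifies the closed form satisfies the ODE to < 1e-9.
* **Biexponential rate.** dQ/dt = kb1·Qb1·e^(−kb1·t) + kb2·(Dose−Qb1)·e^(−kb2·t),
  the exact derivative of the cumulative form.
* **"Higuchi" exponent 0.45.** The Korsmeyer–Peppas special case labelled
  Higuchi uses n = 0.45 — the conventional power-law exponent for these
  cylindrical devices — rather than the classical square-root 0.5. The
  classical law is still available as Korsmeyer–Peppas with n = 0.5.
* **Hixson–Crowell depletion.** Q = Qhc − (Qhc^{1/3} − khc·t)³ is only
  physical up to the depletion time Qhc^{1/3}/khc; past it the cube would
  regrow. Evaluation past depletion clamps Q at Qhc, zeroes the rate, and
  emits a `DepletionWarning`.
* **Time base.** Days everywhere; month-denominated inputs convert at
  30.44 days/month (365.25/12).

## Input functions and the (1−f) correction

Residual-drug data from devices worn five years show that only about half
the load is ever released, so the input functions scale by the releasable
fraction (1−f), f = 0.50 by default (`ImplantSpec.f`; f = 1 is the
degenerate sealed-device case):

    Li(t) = (1−f)·Dose·e^(−k1·t)
    Li(t) = (1−f)·(Qb1·e^(−kb1·t) + (Dose−Qb1)·e^(−kb2·t))

Li(t) is the releasable amount still in the device; −dLi/dt is the input
rate and integrates to (1−f)·Dose.

There is a genuine ambiguity in the biexponential case: the fit treats the
full load (Dose = 150 mg) as the asymptote, so applying the (1−f) prefactor
on top halves the implied release. Both behaviours are exposed through the
`convention` argument — `"corrected"` (the prefactor as written above, the
default) and `"fitted"` (amplitudes used as fitted, no prefactor). The
default is deliberately the literal corrected form; users who fit with
Dose fixed at the full load and want mass consistency should use
`"fitted"` or refit with Qmax-style bounds. The discrepancy is documented
rather than silently resolved.

## Estimation

* **Objective.** SSE = Σ(q − Q(t))² + w·Σ(r − dQ/dt(t))² over amount and
  rate observations. Default w = (mean amount / mean rate)², so one rate
  point contributes like one amount point after scale normalisation; w is
  configurable and echoed in the result.
* **Optimizer.** `scipy.optimize.least_squares` (trust-region reflective)
  within data-scaled bounds, ftol = xtol = gtol = 1e-10. Jacobians are
  finite-difference; at these tolerances the noise-free recovery tests pass
  at machine precision for every family, so analytic Jacobians were not
  needed. Invalid parameter regions return large finite residuals so the
  optimizer never sees NaN/inf.
* **Starting values (auto).** Asymptote-like amounts start at 0.5·dose;
  rate constants at 1/t_max of the data (staggered ×3/÷3 when a family has
  two rate constants, so the phases can separate); exponents at 0.5;
  power-law coefficients scaled so Q(t_max) ≈ 0.5·dose. Bounds keep rate
  constants in [1e-7, 1]/day and amounts in (0, dose].
* **Goodness of fit.** R² = 1 − SSE/SST with SST from the *amount*
  observations about their mean only; rate observations are auxiliary
  (they inform the fit but not the variance decomposition). Adjusted
  R² = 1 − (1−R²)(n−1)/(n−p−1) with n the total observation count and p
  the number of free parameters. Ranking is by adjusted R², ties to the
  smaller p, non-converged fits last.
* **Uncertainty.** Wald/linearised: cov = σ̂²(JᵀJ)⁻¹, σ̂² = SSE/(n−p),
  t-quantile intervals. Singular JᵀJ falls back to a pseudo-inverse and is
  flagged (`covariance_singular`). Intervals may legitimately span negative
  values for weakly identified parameters (sparse biexponential fits).
  Prediction bands use the delta method, half-width t·sqrt(σ̂² + gᵀCg).
  These linearised intervals are approximate for strongly nonlinear
  families; a Monte-Carlo test shows ≈95% coverage for first-order fits
  under the default synthetic design.

## Reduced PK model

The organ-level physiological framework that implant input functions are
ultimately used in is replaced by a two-state linear system: a subcutaneous
depot fed by −dLi/dt and drained at ka into a central compartment with
clearance CL and volume V. This keeps the object under study — the input
function — exact, while lumping distribution physiology into two constants.
Consequences: no tissue partitioning, no binding-protein dynamics, no
DDI/BMI scenarios; the terminal phase is governed by the slowest of
{release constant, ka, CL/V}, which for these implants is the release
constant (flip-flop kinetics).

Defaults (placeholders, to be replaced by literature values for real use):
ka = 0.5/day, CL = 114.29 L/day, V = 260 L, F = 1. They are calibrated only
so that a 0.03–0.04 mg/day input yields Cavg ≈ 260–350 pg/mL, the range
reported for LNG implants at steady state. Concentrations are reported in
pg/mL (1 mg/L = 10⁶ pg/mL), the physiological scale for LNG.

Integration uses LSODA at rtol 1e-8 / atol 1e-12 with the mass ledger
(released, absorbed, eliminated) carried as extra states; balance closes to
< 1e-6 mg over five simulated years, and the first-order-input solution
matches the closed-form tri-exponential to ~1e-6 relative.

The adequacy rule accepts a simulated point when it is within 1.25× the
stated error of the observation, |pred − obs| ≤ 1.25·error; with error = 0
only exact matches pass, so noise-free checks must evaluate the profile on
a grid containing the observation times.

Population variability is lognormal and multiplicative per named parameter
(release constants and/or ka, CL, V), median-preserving (log-mean 0), with
no parameter correlations. Percentile bands (2.5/50/97.5 by default) are
computed per time point across subjects; identical seeds give bitwise
identical bands.

## Synthetic data

`generate_ex_vivo` draws per-device residual amounts dose − Q_true(t) + ε
at each visit, truncates to [0, dose], and reports mean released amount,
SE = sd/√n and n — the summary form in which device-removal studies are
published. Defaults: 13 visits over 0–1825 days (quarterly through year 1,
then semi-annual), 5 devices per visit, additive ε with sd 2 mg (error bars
of a few mg, matching published plots). These defaults are this package's
assumptions about a plausible design — the real studies' schedules are not
tabulated anywhere — and are fully configurable. `generate_label_rates`
evaluates the true rate at months 1/12/24; `generate_plasma_observations`
simulates concentrations at the truth and applies proportional error.

What passing tests show: the estimator recovers generating parameters from
data with this structure, intervals have near-nominal coverage under the
assumed Gaussian noise, and the pipeline is internally consistent
end-to-end. What they do not show: performance on the real historical
datasets (inter-subject heterogeneity, non-Gaussian assay error, informative
visit schedules), or the adequacy of the reduced disposition model for any
particular drug — those require real data and literature PK parameters.

Truncation at the physical range biases the mean upward where Q_true is
near 0 or the full releasable amount (most visibly at t = 0); the generator
warns when more than half of all draws are truncated. Noise-sensitive
simulation studies in the test suite therefore start sampling at day 91.

## Numerical edge cases

* Power-law rates at t = 0 return the correct limit (∞ for exponent < 1,
  the coefficient at 1, 0 above 1); fitting uses rate observations at
  t > 0 only.
* Q(0) is exactly 0 for every family (the Hixson–Crowell cube is clamped
  against ~1e-14 float residue).
* Bounded families approach their asymptote to within float precision at
  very large t; strict inequality is only meaningful at representable
  distances from the bound.
* Degenerate degrees of freedom (n − p − 1 < 1) raise rather than return
  an undefined adjusted R².

## Problem sizes

Default test and example sizes — 13-point designs, 500-replicate coverage
runs, 1000-subject short-horizon population checks, daily 5-year grids —
were chosen so the full suite completes in well under a minute on one core
while keeping Monte-Carlo tolerances tight (±4 percentage points on
coverage at 500 replicates, ±3% on a 1000-subject median).
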