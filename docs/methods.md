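# Methods

## Structural model

The oral dose starts entirely in the tablet. Release follows
Michaelis–Menten depletion of the dose-normalized tablet amount
(`vmax_invivo` in 1/h, `am50_invivo` as a fraction of dose), multiplied by
a time-varying dissolved fraction that encodes where the tablet is in the
gastrointestinal tract:

- `f_diss_stomach(t) = 1 − I_max·t^h_s/(T_GET^h_s + t^h_s)` — dissolution
  capacity is full at gastric pH and collapses by `I_max` around the
  gastric-emptying half-time `T_GET`, with Hill steepness `h_s`.
- `f_diss_intestine(t) = Diss_max · rise(t; T_trans1) · fall(t; T_trans2)`
  — a bounded rebound during colonic transit, with
  `T_trans1 = T_GET + T_ITT` and `T_trans2 = T_GET + T_ITT + T_CTT`.
- `f_diss_total = f_diss_stomach + f_diss_intestine`; `0^h` is taken as 0
  by continuous extension, so the trajectory starts exactly at 1.

Dissolved drug transfers lumen → gut → central at first order (`k_lag`,
`k_a`); disposition is a linear two-compartment model. Tablet/lumen/gut
states are fractions of dose; absorption multiplies by the dose (mg), and
the plasma concentration is `x1/v1 × 1000` ng/mL. The printed estimates
for sildenafil in fasted Beagle dogs used as package defaults live in
`popivivc.defaults`, together with the study's sampling schedules.

With the default (dog) parameters the dissolved fraction falls to a
minimum of ~0.8% after gastric emptying, rebounds above 10% between
~3.2 and ~6.3 h, and collapses again — which is what caps the 12-h in-vivo
dissolution of the medium and slow sustained-release tablets and produces
their secondary plasma peaks. The immediate-release tablet finishes
dissolving before the window and stays single-peaked.

A bookkeeping state (cumulative amount eliminated) closes the mass
balance, so conservation is a testable invariant rather than an article of
faith.

## Numerics

Two integration paths share one right-hand side:

- `lsoda` (default for `simulate_pk`/`simulate_dense`): adaptive,
  stiff-capable, rtol 1e−8 / atol 1e−10, step capped at 0.05 h so that the
  near-switch Hill terms (exponents > 13) are never stepped over.
- `rk4`: a compiled fixed-step classical Runge–Kutta (default step
  0.005 h, 0.02 h inside estimation loops). Runge–Kutta methods preserve
  linear invariants, so mass balance holds to machine precision; agreement
  with the adaptive path is ~1e−6 ng/mL at the default step and ~3e−4
  ng/mL at 0.02 h. This path exists because a population fit needs ~10⁵
  trajectory evaluations.

Cmax is read from a dense 0.01-h output grid (documented error < 0.5%
given the model's absorption rates). The in-vitro Michaelis–Menten curve
is evaluated through its implicit integrated form
`vmax·t = am50·ln(1/x) + (1−x)` solved by bracketed root finding, and is
cross-checked against an ODE integration in the tests; the inverse map
(time to reach a given fraction dissolved) is closed-form.

## Estimation

`fit_invitro_mm` pools vessels (pH 1.2 by default, the condition where
Michaelis–Menten kinetics describe the data), normalizes percent to
fraction of dose, and runs multi-start least squares in log space (vmax
started at the maximal observed release slope; am50 from {0.1, 0.3, 0.5};
ties broken toward the smallest am50). For tablets that finish dissolving
before the second sampling point the (vmax, am50) pair is a ridge;
`fit_invitro_mm_joint` therefore fits all formulations together with one
shared am50 (a drug/medium property) and one vmax per formulation, which
is also how the reference estimates are tabulated. The CLI and the
analysis pipeline use the joint fit.

`fit_popk` is an importance-sampling Monte Carlo EM for the nonlinear
mixed-effects model with log-normal between-subject variability (diagonal
ω²) and proportional residual error:

- **E-step.** Per subject, the conditional mode of η is found by
  warm-started Levenberg–Marquardt on the stacked (data + prior)
  residuals (multi-start in the first iteration); the proposal is a
  defensive mixture of a multivariate-t (df 4) with the Laplace
  covariance at the mode and a wide prior-scale normal component, which
  keeps importance weights bounded and lets the sampler escape local
  posterior basins. Samples whose parameters overflow the fixed-step
  integrator get zero weight.
- **M-step.** θ moves by the (clipped, ±0.25 log units) mean posterior
  η; ω² by the damped posterior spread (floored at 1e−4 so proposals stay
  alive, capped at 4); σ by the damped root-mean-square proportional
  residual, held for the first two iterations while proposals are still
  diffuse. Optionally the final θ is the geometric mean of the trailing
  iterates, which damps Monte Carlo jitter.
- **Censoring.** Observations below the LLOQ are excluded from the
  likelihood by default (M1). An M3 option instead adds the censored
  contribution Φ((LLOQ − f)/sd); simulation shows M1 visibly biases CL
  down and V2 up on this design (only upward-noise tail observations
  survive censoring), so recovery studies here use M3.
- The run is deterministic given the seed, reports the importance-sampled
  marginal log-likelihood per iteration with a delta-method Monte Carlo
  standard error, and returns `converged=False` loudly when the relative
  parameter change never stays under the tolerance.

All formulations are fitted simultaneously; every parameter is shared
except the in-vivo release rate, which is per-formulation.

`conditional_mode` exposes the empirical-Bayes step: with all ω² = 0 it
returns the population-typical subject, and it falls back to the means
with a warning if the mode search fails.

## IVIVC and validation

`fit_power_ivivc` fits `y = a·x^b + c` between dose-normalized in-vitro
and in-vivo maximum release rates by multi-start least squares, fitting
the linear form alongside for comparison (r² on the untransformed scale).
Because the rates span almost two orders of magnitude, residuals are
weighted by the observed rate by default ("relative"); this weighting is
what reproduces published power-law coefficients for this system, and
ordinary least squares is available via `weighting="none"`.
`convert_vmax` maps an in-vitro rate through the fitted law, warning on
extrapolation and refusing non-positive outputs. `predict_from_invitro`
simulates either the population-typical subject (default, used for the
reproduction numbers) or a Monte Carlo population with percentile bands.
`validate` scores observed vs predicted Cmax and AUC by
%PE = |obs − pred|/obs × 100 (reported to one decimal), with the
conventional 10% average-%PE threshold annotation.

A three-point, three-parameter power law interpolates its calibration
points exactly and converts reliably *within* the fitted rate range;
leave-one-out refits predict the faster formulations' Cmax within ~10%
but cannot extrapolate below the slowest calibrated rate. Predicting a
new formulation is therefore trustworthy only inside (or near) the
calibrated release-rate range.

## Synthetic data

The generator emulates the study design: four formulations (IR 20 mg,
three SR at 60 mg), 3 subjects each, 19 plasma samples over 48 h censored
at 5 ng/mL, and 6 dissolution vessels sampled 14 times over 24 h.
Individuals are drawn from the exponential variability model; plasma
observations carry proportional noise (default CV 0.15 — the source
analysis reports no residual magnitude, so this is a package choice at the
upper end of typical LC-MS/MS plasma assays); dissolution observations
carry additive noise in percent points (default 2), clipped to [0, 105]%.
Every generator is a pure function of (parameters, design, seed) and
returns ground truth alongside the data.

What the generator does *not* emulate: inter-occasion variability, food
effects, correlated random effects, model misspecification (the fitted
model is the generating model), and pH 4.5/6.8 incomplete-dissolution
mechanics. Passing recovery tests therefore demonstrate estimator
correctness under the assumed model, not robustness to structural error in
real dog data.

## Recovery studies and their problem sizes

The noiseless study (no variability, residual CV 1e−6, 12 subjects)
recovers every estimated fixed effect to well under 2%.

The noisy study uses the printed between-subject variances as ω², which
imply CVs up to ~100%. The population mean estimated from 12 subjects then
has an irreducible sampling SE around 25% for the most variable
parameters, so any single replicate scatters widely no matter the
estimator; recovery is therefore scored on the per-parameter geometric
mean across 20 replicate cohorts, which isolates estimator bias from
design-limited sampling noise. In these studies the three shape
parameters (I_max and the two Hill exponents) are held at their
generating values — steepness of a switch is not identifiable from
19-sample profiles — and ω² is held at the generating values because the
question is fixed-effect recovery. Estimation runs use 150–250 importance
samples per subject, 20–30 EM iterations, the 0.02-h integrator step and
trailing-iterate averaging; these sizes were chosen to resolve the
estimator's bias structure while keeping a 20-replicate study on one CPU
in minutes.

A related finding from the end-to-end pipeline: with 3 subjects per arm
and the reference variances, the realized arm means can rank-invert the
formulations' exposure, in which case no monotone rate correlation can
meet a 10% average internal-predictability level. Sample-size (not
estimator) limitations of this kind are exactly what the synthetic
pipeline is meant to expose.

## Known limitations

- The correlation attaches the entire formulation effect to V_max; AM_50
  is shared. Formulations whose mechanism changes AM_50 are outside the
  model.
- M1 censoring (the default) biases terminal-phase parameters when a
  profile's tail is largely censored; use `blq="M3"` when that matters.
- lambda_z selection maximizes adjusted r² over terminal suffixes; for
  absorption-limited (flip-flop) profiles it reports the apparent, not
  the disposition, rate constant.
- The linear trapezoid (default, matching common practice) overestimates
  AUC on sparsely sampled exponential tails by a few percent; the
  log-linear-down variant is exact on exponential declines.
- ω² estimation by this EM is noisy at n = 12 and is reported but not
  validated to a tolerance; only fixed effects carry recovery guarantees.
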