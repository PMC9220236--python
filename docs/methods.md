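# Methods

## Scope

`sparse_pkpd` is a simulation–estimation workbench for a single question:
what happens to population pharmacokinetic (PK) parameter estimates, and to
the downstream AUC/MIC exposure predictions that guide vancomycin dosing,
when a structural model with too few compartments is fitted to sparsely
sampled concentration data?  The package simulates virtual patients from
published two- and three-compartment vancomycin models, re-fits reduced
models to subset sampling designs with its own FOCE-I estimator, and
propagates the fitted parameters through Monte Carlo evaluation of
steady-state AUC24/MIC target attainment.

## Structural models

All kinetics are linear mammillary compartment models with elimination from
the central compartment and zero-order (constant-rate) IV infusion input.
Parameters are clearances and volumes: CL, V1, plus (Q1, V2) for two
compartments and (Q2, V3) for three.  Micro-constants follow the usual
convention k10 = CL/V1, k12 = Q1/V1, k21 = Q1/V2, k13 = Q2/V1, k31 = Q2/V3;
amounts are propagated and concentration is the central amount divided by V1.

Profiles are computed from the eigendecomposition of the rate matrix A.
Because a mammillary matrix is symmetrised by the volume scaling
D = diag(1/√V), its eigenvalues λk are real and negative, and the central
concentration after a unit-rate infusion of duration D is a sum of modes

    c(t) = (R / V1) · Σk  ak · exp(λk (t − D)+) · (exp(λk min(t, D)) − 1)/λk

with amplitudes ak that reduce to squared eigenvector components in the
symmetrised basis (for two compartments the closed-form quadratic roots are
used directly).  The periodic steady state under a dosing interval τ is
obtained in closed form in the same eigenbasis — each mode accumulates by
the geometric factor 1/(1 − exp(λk τ)) — rather than by long superposition;
superposition is retained as a test oracle.  Exact-arithmetic identities
used throughout: Vss = ΣVi and AUC24 = (24/τ)·dose/CL for linear kinetics.

Cmax is defined as the maximum of the steady-state profile on a 0.01 h grid
over one interval rather than the end-of-infusion value, so that the same
definition holds for every model order (with distribution phases the peak
need not sit exactly at the end of infusion).  Cmin is the concentration at
t = τ, the pre-dose trough, matching clinical convention.

## Synthetic-data generator

The generator defines the study conditions:

* **Population models.**  Two published vancomycin models with typical
  values (2-cmt: CL 2.83 L/h, V1 24.2 L, Q1 11.2 L/h, V2 32.3 L; 3-cmt:
  CL 4.01 L/h, V1 8.01 L, Q1 4.95 L/h, V2 15.4 L, Q2 9.09 L/h, V3 6.21 L),
  between-subject variability (BSV) as %CV on CL/V1 (77%/34%) and on
  CL/V1/V2/V3 (33.9%/27.9%/34.3%/56.9%), and proportional residual error
  (8.19% and 6.64%).
* **Covariates.**  The published covariate relations (creatinine clearance
  on CL, body weight on volumes, estimated GFR on CL) are carried with
  their centering medians and fixed there, so every covariate multiplier is
  exactly 1 and covariates drop out of both simulation and estimation.
* **Between-subject variability.**  Parameters are log-normal,
  Pi = TV·exp(η), with η ~ N(0, ω²) truncated at |η| ≤ 2ω by rejection
  sampling.  The reported %CV maps to the log-scale SD as ω = CV — the
  dominant convention for quoting NONMEM ω estimates as percentages; the
  exact mapping ω² = ln(1+CV²) is available as an option
  (`PopulationPKModel.omega(..., cv_convention="lognormal_exact")`).  Under
  ±2 SD truncation the realised variance is 0.774·ω²; tests check empirical
  CVs against a numeric-integration oracle for the truncated distribution.
* **Residual error.**  Observations are DV = C·(1+ε), ε ~ N(0, σ²),
  untruncated.  A negative DV (vanishingly rare at ≤8.19% CV) is floored at
  0 and flagged MDV=1.  Pre-dose t = 0 samples are recorded with DV = 0 and
  MDV = 1: a zero concentration carries no likelihood information under a
  purely proportional error model, so these rows are excluded from fitting.
* **Designs and regimens.**  Single-dose 1 g infusions (2 h for the 2-cmt
  truth, 1 h for the 3-cmt truth) sampled at the study's rich designs
  (0, 2.5, 3, 4, 6, 8 h and 0, 1, 1.5, 2, 3, 4, 6, 8, 12 h).  Reduced
  designs are strict subsets of the simulated records — the same noisy
  values are kept, nothing is re-simulated — pairing 4-point designs with
  1-compartment fits and 6-point designs with 2-compartment fits.

Datasets use the NONMEM-style rectangular layout (ID, TIME, AMT, RATE, DV,
EVID, MDV) and round-trip through CSV with a JSON sidecar recording the
seed, model and design.

What the generator does *not* emulate: covariate distributions (fixed at
medians by design), within-subject parameter variability, multiple-dose
accumulation in the observed data (profiles are single-dose, as in the
source protocol), assay quantification limits, and model misspecification
beyond compartment count.  Passing tests therefore demonstrate estimator
behaviour under the stated idealised conditions, not performance on
clinical TDM data.

## FOCE-I estimation

The estimator is first-order conditional estimation with η–ε interaction,
re-implemented from its standard definition (NONMEM is not called).  Random
effects are diagonal log-normal on a configurable subset of structural
parameters; the residual model is proportional.

* **Inner problem.**  Each subject's conditional mode η̂ minimises
  Σj [ln(σ²fj(η)²) + (yj − fj(η))²/(σ²fj(η)²)] + η'Ω⁻¹η.  All subjects are
  solved simultaneously by a damped Gauss–Newton iteration (forward-
  difference Jacobians, full ∂²/∂f² weights clipped positive, vectorised
  backtracking; steps capped at 5 and η at ±20 to keep exp(η) finite).
* **Objective.**  The population objective linearises f around η̂ and
  evaluates the residual variance at η̂ (the "interaction"):  per subject
  −2LL ≈ ln det C + r'C⁻¹r + nobs·ln 2π with C = JΩJ' + diag(σ²f(η̂)²) and
  r = y − f(η̂) + Jη̂.  Including the 2π constant keeps the value comparable
  to the exact marginal likelihood; tests verify agreement within 2% of
  adaptive quadrature on single-η subjects.
* **Outer problem.**  Quasi-Newton (L-BFGS-B) on log θ, log ω², log σ²
  (positivity by construction, bounds ±12 in log space) of the
  per-observation objective — scaling the objective keeps the initial
  line-search step sensible.  The conditional-mode warm start is frozen
  during finite-difference and line-search evaluations and refreshed once
  per accepted iterate; this makes the objective surface consistent under
  re-evaluation, which the line search requires.  Up to five jittered
  restarts (seeded) run on optimizer failure.  Convergence is the
  optimizer's success status; the accepted-iterate objective trace is
  retained and is non-increasing up to evaluation jitter (~1e-4).
* **Initial estimates.**  CL from dose over the trapezoidal AUC of the
  pooled mean profile with log-linear tail extrapolation; V from dose over
  the peak mean concentration; peripheral compartments seeded as fractions
  of V; ω² at 0.1 and σ² at 0.02.
* **Random-effect structure.**  Mirrors the generating models where orders
  match (2-cmt: η on CL, V1; 3-cmt: η on CL, V1, V2, V3); reduced models
  carry η on CL and V1.  Ω is diagonal throughout.
* **Identifiability guard.**  A spec with k structural parameters requires
  at least k distinct usable observation times per subject; fitting a
  3-compartment model to a 4-point design raises an error rather than
  returning an unidentified fit.  This mirrors the study's pairing of the
  9-point design with 3-compartment fits.

Estimation operates on the single-dose records; empirical Bayes parameter
sets Pi = θ·exp(η̂i) are produced at the optimum.

## Bias and precision

Across replicate fits, RBias(%) = 100·mean((θi − θT)/θT) and
RRMSE(%) = 100·√mean(((θi − θT)/θT)²) against the simulation truth, with
Vss aggregated from fitted volumes (V1, V1+V2, V1+V2+V3; truths 56.5 L and
29.62 L).  RBias is reported signed; the conventional acceptance thresholds
(|RBias| ≤ 15%, RRMSE ≤ 35%, both inclusive) are applied to magnitudes.
Unconverged fits are excluded from the metrics and counted in the run
metadata rather than re-simulated.

## AUC/MIC target attainment

Individual parameter sets are pooled across the n = 50 replicate fits —
the per-subject empirical Bayes estimates, 200 fits × 50 subjects = 10,000
individuals at full scale.  Pooling EBEs makes the 10,000-individual count
an exact consequence of the design; re-simulating virtual subjects from
each fitted population distribution is available as an option
(`pta_from_fits(..., source="simulated")`).  For each dose (0.5, 0.75, 1 g
every 12 h, infusion duration matching the truth model's regimen) the
steady-state AUC24 = 2·dose/CL is binned by AUC/MIC at MIC 1 mg/L into
<400, 400–600 and >600, with both edges inside the middle bin (boundary
hits have probability ~0 for continuous parameters).  Probabilities are
percentages of pooled individuals and sum to 100 before rounding.

## Problem sizes and determinism

The package exposes one code path for desk-scale and full-scale studies;
replicate count, sample sizes and doses are configuration.  The test suite
and the acceptance script run the desk-scale study: 20 replicate datasets
per scenario (instead of 200) at the study's subject counts (n = 50, plus
n = 12 and n = 100 where those cells are checked), which keeps a full run
in the minutes range on one CPU while leaving Monte Carlo error well inside
the stochastic tolerances used for comparison.  Every random draw descends
from one master seed through `numpy` SeedSequence spawning keyed by
(seed, truth order, sample size, replicate), so dataset seeds are shared
across fitted model orders — different models are fitted to the same
simulated profiles, as in the source protocol — and any study slice can be
re-run independently and bit-identically.

## Known limitations

* FOCE-I implementation details (centred vs hybrid linearisation, exact
  convergence criteria) differ from NONMEM's; matched-order typical-value
  estimates agree well, but variance components and borderline-identifiable
  cells can differ at the percent level.
* The 2×2 closed-form eigenvalues and the clipped Gauss–Newton weights
  assume strictly positive parameters; degenerate repeated-eigenvalue
  inputs are guarded by floors rather than handled analytically.
* Standard errors of estimates are not computed (none are compared), and Ω
  is diagonal only.
* Cmax on a 0.01 h grid is exact to ~1e-4 mg/L for these kinetics; the
  grid step is a module constant (`pk_core.CMAX_GRID_STEP`).
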