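# Methods

## Structural model

Meropenem disposition is described by three compartments: central
(serum), peripheral tissue, and CSF, with amounts X₁, X₂, X₃ (mg):

    dX₁/dt = R(t) − (CL/V_c)·X₁ − k_cp·X₁ − k_cb·X₁ + k_pc·X₂ + k_bc·X₃
    dX₂/dt = k_cp·X₁ − k_pc·X₂
    dX₃/dt = k_cb·X₁ − k_bc·X₃

R(t) is the summed zero-order infusion rate (mg/h). Elimination is
linear from the central compartment only; the CSF compartment has no
elimination route of its own (drain losses are not modelled). Observed
outputs are serum = X₁/V_c and CSF = X₃/V_CSF. V_CSF is an apparent
scaling volume — "the number that maps CSF amounts to the low observed
CSF concentrations" — not an anatomical volume.

The central→CSF outflow uses k_cb. (Source material prints the
subscript of that one term inconsistently; the mass-balanced form, in
which the flux leaving the central compartment equals the flux entering
the CSF compartment, is the only self-consistent reading.) Rate
constants are 1/h throughout; the summary table's "L⁻¹" unit label for
them is treated as a typographical slip, since the differential
equations require 1/h.

Parameters (units, default box for estimation):

| name  | meaning                        | box           |
|-------|--------------------------------|---------------|
| CL    | serum clearance, L/h           | 1 – 35        |
| V_c   | central volume, L              | 1 – 20        |
| k_cp  | central→peripheral, 1/h        | 0.01 – 5      |
| k_pc  | peripheral→central, 1/h        | 0.01 – 5      |
| k_cb  | central→CSF, 1/h               | 0.001 – 0.5   |
| k_bc  | CSF→central, 1/h               | 0.001 – 0.5   |
| V_CSF | apparent CSF volume, L         | 20 – 150      |

The box spans the cohort's reported ranges with margin and is
overridable.

### Numerical solution

The system is linear with piecewise-constant input, so between any two
infusion on/off switches the augmented 4×4 system (state ⊕ constant
input) is propagated exactly with `scipy.linalg.expm`. Segment
operators are cached per (step length, rate) pair and evaluated for
whole parameter batches at once, which makes population-scale
likelihood evaluation cheap on regular sampling grids. An adaptive
stiff integrator (`solve_ivp`, LSODA at rtol 1e-10) serves as the
independent oracle in the test suite; agreement is at 1e-6 relative.

Steady state is declared when serum and CSF troughs change by <0.1%
(relative) between successive dosing intervals, capped at 50 intervals.
The cap matters only for parameter sets with CSF elimination half-lives
near 70 h, which sit ~2% below their asymptote at the cap; the effect on
any reported quantity is negligible (verified against the exact periodic
fixed point). Useful identities of the linear model, used as tests:
steady-state serum AUC per interval = dose/CL, and steady-state
AUC_CSF/AUC_serum = (k_cb·V_c)/(k_bc·V_CSF).

## Observation error model

Total SD for an observation y on output o is

    sd_o(y) = c0_o + c1_o·y + λ

with defaults c0 = 0.25 mg/L (serum) and 0.10 mg/L (CSF) — half the
assay LOQs of 0.5 and 0.2 mg/L — c1 = 0.05 (the assay's <5% relative
SD), and a fixed additive λ = 0.2 mg/L absorbing process noise (dosing
and sampling-time errors). The source bioanalytics never print their
error polynomial, so these are declared defaults, configurable
everywhere. Likelihood weighting is by the inverse variance evaluated at
the *observed* value, making each observation's weight a fixed constant;
this keeps the maximum-likelihood fit of noise-free data at zero
residual (weighting at the prediction would bias the optimum by ≈ −c1·sd
because inflating the prediction inflates its own variance).

Below-LOQ (BLQ) observations are imputed at LOQ/2 by default; a censored
mode replaces the density by the normal CDF at the LOQ. The default was
chosen for robustness and comparability; the censored mode is exact
under the model.

## Nonparametric population estimation

The population distribution F over the 7 parameters is estimated
nonparametrically as a discrete distribution (support points + weights)
maximizing the pooled marginal likelihood Σᵢ log ∫ Lᵢ(θ) dF(θ) — the
NPML problem, whose solution needs at most one support point per
subject. The implementation follows the adaptive-grid strategy:

1. **Initial grid** — 2ⁿ scrambled Sobol points in the box (default
   2¹¹; scaled-down problem sizes are used in the test suite).
2. **Weights** — for fixed support the weight problem is convex on the
   simplex; it is solved by the classical multiplicative EM update
   w_j ← w_j·meanᵢ(L_ij/(Lw)ᵢ), which is monotone. Subject rows are
   max-shifted in log space before exponentiation to avoid underflow.
3. **Condense/expand** — points below 10⁻³ of the maximum weight are
   dropped; each survivor is perturbed ±f·(box width) in every dimension
   (f starts at 0.2 and halves whenever a cycle's gain falls below the
   tolerance); per-subject posterior means/medians are added as
   correlated candidates. Cycles that improve the log-likelihood are
   accepted, so the reported trace is non-decreasing by construction.
4. **Location polish** — after the grid loop, an EM stage alternates
   responsibilities with an M-step that moves each heavy support point
   by L-BFGS-B in log-parameter space (gradient by central differences,
   evaluated in one batched model call). This follows the narrow curved
   valleys — notably the (k_cb, V_CSF) trade-off — that one-dimensional
   grid moves cannot track. Rounds not improving the marginal
   log-likelihood are discarded (generalized EM).

Bayesian post-hoc individual estimates reweight the population support
by each subject's likelihood; the per-dimension weighted median is the
reported individual parameter. Fit diagnostics are r² of observed vs
posterior-predicted concentrations per output, plus the mean (bias) and
variance (imprecision) of inverse-SD-weighted errors.

Covariate screening computes Spearman's ρ (with two-sided p) of every
numeric covariate against every posterior-median parameter and exports
the pairs for plotting. No automatic inclusion machinery is built: the
workflow this mirrors assessed covariates visually and retained none.

## Identifiability and the recovery benchmark

Two directions of parameter space are intrinsically soft at this drug's
penetration level. (k_cb, V_CSF) scale jointly with almost no effect on
either observed output when CSF holds little drug mass (only the small
back-flux k_bc·X₃ into serum separates them); and the peripheral and
CSF compartments can trade mass when their return time constants are
similar. Consequently the parameter-recovery benchmark — 40 subjects
drawn from a two-point population, fitted blind — uses truth points with
(i) CSF coupling strong enough that the CSF reservoir carries
appreciable mass, (ii) peripheral return several-fold faster than CSF
return, and (iii) distribution exchange slow enough for quarter-hour
sampling to resolve, plus a rich schedule (samples every 15 min through
the infusion and early washout, ~28/day over 7 days, both outputs).
Under those conditions the fit recovers every dimension of both support
points to within ~10% and the weights to within a few percent. At the actual
study's sparse trough/peak sampling and ~9% penetration, V_CSF and k_cb
are individually much more uncertain (their ratio is what the data
determine) — consistent with the source describing V_CSF as merely a
scalar.

## Synthetic cohorts

The generator emulates the study: 2000 mg q8h as 4-h infusions (1000 mg
when Cockcroft-Gault CrCL ≤ 50 ml/min), paired trough/end-of-infusion
serum and CSF samples daily on days 1–3 then every 2–3 days over a
7-day span (10 samples per fluid per subject, matching the real ~10 per
patient), covariates drawn from the reported ranges (age 46–80 y, weight
55–105 kg, CrCL ~48–220 ml/min), Gaussian noise from the error model,
and BLQ flagging below the LOQs (negative noisy values are censored
BLQ rather than resampled — simplest and unbiased at the LOQ).
Covariates are independent of PK parameters by default, mirroring the
null covariate finding; a hook can inject a known effect to power-test
the screen. What passing tests on such cohorts do *not* show: behaviour
under model misspecification, nonlinear transport, drain-flow CSF
losses, or real assay error structure.

## Monte Carlo target attainment

Virtual patients are sampled either by i.i.d. resampling of a discrete
set (population support points, or the 21 per-patient sets reconstructed
from the printed individual results) or from independent log-normals
moment-matched to the printed population mean/SD and truncated to the
box. Each draw runs to steady state under the candidate regimen; the
attainment metric is the steady-state CSF trough (end of interval, all
CSF drug taken as unbound), compared with targets 1/2/4 mg/L using ≥.

The reconstruction of the 21 patient sets takes CL and V_c directly,
k_cb = ln2/t½cb and k_bc = ln2/t½bc from the printed half-lives, V_CSF
from the steady-state identity V_CSF = (k_cb·V_c)/(k_bc·ratio), and the
population-median k_cp, k_pc (not printed per patient). It is the only
route to patient-level joint parameter sets from the published tables,
and it is approximate: printed values carry two-decimal rounding, and
the published fit's own joint distribution (support points and weights)
was never printed. The printed per-patient data bound what any faithful
resampling can give: the implied steady-state average CSF concentration
is ratio × (daily dose)/(24·CL), which at 2000 mg q8h exceeds 2 mg/L for
only ~5–6 of the 21 patients. Attainment percentages computed here are
therefore internally consistent with the printed individual exposures
(and with the observed CSF troughs), but an external simulation drawn
from the unpublished joint can differ substantially.

## Problem sizes and reproducibility

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical
cohorts, draws and PTA tables. Default problem sizes: 1000 simulated
patients per PTA run (averaged over 5 seeds in the acceptance script),
2¹¹-point initial grids for production fits, 2⁹ for the recovery
benchmark, 0.25-h grids for profile exports and 0.05-h grids for
steady-state interval profiles. Every CLI output embeds the seed and a
hash of the run configuration.

## Known limitations

* Linear transport only; saturable blood–CSF carriers would need a
  different structural model.
* No CSF drain elimination term, although drained volume is recorded as
  a covariate.
* The error polynomial and λ are declared, not estimated; λ is held
  fixed during fitting.
* NPML point estimates carry no uncertainty quantification here
  (no bootstrap).
* The published fit cannot be reconstructed exactly from printed
  marginals; see the Monte Carlo section above.
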