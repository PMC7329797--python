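# Methods

This note documents the modelling assumptions, numerical choices and known
limitations of the package. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Structural model

Plasma meropenem in CRRT patients is described by a linear two-compartment
mammillary model with zero-order infusion input into the central
compartment and elimination exclusively through the CRRT circuit
(clearance `Cl_CRRT`, l/h). Renal and non-renal clearance are not modelled
separately: the study population is anuric/oliguric on continuous
hemofiltration or hemodialysis, and the data cannot distinguish the
routes. Sieving/adsorption by the filter membrane is likewise not resolved
— `Cl_CRRT` is the lumped systemic clearance.

The production path evaluates the closed-form bi-exponential solution:
the hybrid rate constants α, β are the roots of
x² − (k10 + k12 + k21)x + k10·k21 with k10 = Cl_CRRT/V1, k12 = Q/V1,
k21 = Q/V2, and the unit-bolus central response is
A·e^(−αt) + B·e^(−βt), A = (α − k21)/((α − β)V1), B = (k21 − β)/((α − β)V1).
A single expression covers the during- and post-infusion branches of each
dose and superposition handles arbitrary schedules. Steady state uses
geometric accumulation of the exponential terms over infinitely many prior
doses; an explicit-superposition path (≈27 terminal half-lives of doses,
residual accumulation < 1e-8) serves as a cross-check and the two agree to
better than 1e-6 relative.

Numerical edge cases: a repeated root α ≈ β (measure-zero in the parameter
space) is handled by flooring the relative root separation at 1e-9 rather
than switching to the degenerate (A + Bt)e^(−αt) form — the induced error
is O(1e-9), far below every tolerance in the package, and it keeps a
single code path. β is additionally floored at 1e-14·α so that the Q → 0
one-compartment limit explored by the optimizer stays finite. Direct ODE
integration (piecewise across infusion boundaries, DOP853, rtol ≤ 1e-8,
max step 0.25 h so the dense-output interpolant stays as accurate as the
steps) exists only as an independent test oracle.

Units throughout: hours, litres, mg, mg/l (≡ µg/ml); clearances in l/h.

## Population layer

Individual parameters are log-normal around covariate-adjusted typical
values, P_i = θ_P · f(COV_i) · exp(η_P,i). Covariate laws are linear
(1 + β(COV − ref)), power ((COV/ref)^β) or indicator (1 + β·IND); the
reference is frozen at model-build time (dataset median; 24.6 g/l albumin
for the published model) so simulation never re-derives it. The final
published model carries one law — albumin power −2.87 on V1 — and IIV on
V1, Cl and V2; the IIV of Q is structurally zero and Q carries no random
effect at all. Inter-individual variability is reported as the log-normal
%CV = 100·√(exp(ω²) − 1); the eta order is fixed as (V1, Cl, Q, V2).

Residual error is combined additive + proportional,
var = σ_add² + (σ_prop·C)², with σ_add = 0.881 mg/l and σ_prop = 0.241 in
the published model. Simulated observations may be negative through the
additive component; the VPC keeps them (generative fidelity), the cohort
generator clips them at zero and flags the record excluded (the assay
cannot report a negative value), and PTA never uses residual error.

## Estimation

The per-subject marginal likelihood is approximated at the conditional
mode of the random effects, with the residual variance evaluated at the
conditional predictions (the "interaction" convention). The mode is found
by a damped Newton search, batched across subjects: Gauss–Newton curvature
with an exact scalar second-derivative weight (kept positive-definite by
flooring) far from the mode, the exact finite-difference Hessian near it
for quadratic tail convergence, a trust-region cap of 5 on the log-scale
step, and a gradient tolerance of 1e-8.

The −2 log marginal likelihood (OFV) per subject is the Laplace value
(joint −2 log density at the mode plus log-determinants of Ω and of the
exact Hessian); with a single random effect it is refined by 7-node
adaptive Gauss–Hermite quadrature centered and scaled at the mode. This
follows the convention of mainstream mixed-model software (quadrature
refinement only for scalar random effects, Laplace otherwise): on sparse
one-effect problems the refinement reduces the approximation error by an
order of magnitude at negligible cost, while a tensor grid in three
dimensions would multiply the cost of every fit several-fold. All
normalizing constants are kept, so OFV values are directly comparable to
numerical quadrature of the exact joint density.

The outer problem maximizes over log-transformed θ, ω² and residual SDs
(covariate coefficients untransformed) with bounded Powell search;
bounds matter because a variance whose ML estimate is zero never converges
in log-parametrization (ω² is bounded below at 1e-6, which doubles as the
boundary flag the bootstrap counts as "unsuccessful"). Convergence is a
relative OFV change below 1e-6 per Powell cycle. Inner eta modes are
warm-started across outer iterations; the reported OFV is recomputed
cold-started at the optimum so results are path-independent.

Model comparison treats ΔOFV between nested fits as χ²: forward inclusion
at 3.84 (1 df, p < 0.05), backward elimination vetoed above 7.9
(p < 0.005). Stepwise candidate fits are warm-started from the current
model with the new coefficient at zero; ties within 1e-6 resolve
lexicographically by (parameter, covariate, form). Eta shrinkage is
100·(1 − SD(EBE)/ω) with the population SD.

A caution from the package's own experiments: with aggressively shrunken
designs (e.g. 12 subjects × 7 samples) the ΔOFV null distribution is
markedly anti-conservative — a spurious covariate can gain > 7.9 OFV
points by rescuing a fit whose ω²_V2 estimate collapses — so type-I
behavior of the stepwise search should be assessed (and is tested) at the
full study design of 19 subjects × 11 samples, where it behaves per χ²(1).

## Diagnostics

The VPC simulates replicate datasets under the original design (each
subject's doses, sampling times and covariates), bins observed and
simulated values at the nominal time-after-dose (exact times, not quantile
bins, because the design is fixed), and compares observed 5th/50th/95th
percentiles against the simulation 90% band per percentile. Percentiles
use numpy's linear interpolation of order statistics everywhere.

The bootstrap resamples subjects (never observations) with replacement to
the original subject count and refits, warm-started from the original
estimates; non-convergence or a variance on the boundary counts the
replicate unsuccessful, and > 50% failures aborts. Intervals are the
5th–95th percentiles of successful replicates.

Residual diagnostics: IPRED at the EBE mode, PRED at η = 0,
IWRES = (y − IPRED)/√var(IPRED), and CWRES from the conditional
linearization — V = JΩJᵀ + diag(var(IPRED)), expectation F(η̂) − Jη̂,
decorrelated by the lower Cholesky factor of V (the frozen convention).

## PTA simulation

Virtual subjects are drawn from the population model (random effects only;
assay error does not change whether a patient's true concentration exceeds
the MIC), individual steady-state profiles are evaluated on a 513-point
grid over one dosing interval, and the fraction of the interval above MIC
is computed from the piecewise-linear interpolant (exact for segments
wholly above or below; monotone in MIC by construction, which makes the
monotonicity of PTA in MIC, dose and target stringency exact for every
seed). The public `fraction_time_above_mic` refines crossings by
root-finding to 1e-6 h; the grid path agrees with it to ~1e-4 and is used
for the batched simulation. The whole-interval (100%) target reduces to
trough > MIC, and the steady-state trough sits exactly on the grid at t=0.

Total plasma concentration is compared with MIC without a protein-binding
correction: meropenem binding is ~2%, and the study targets are stated on
plasma concentration. The MIC grid is the exact two-fold ladder from
0.064 mg/l with the last rung clipped to 64; MIC-at-90%-PTA interpolates
the crossing linearly in log2-MIC, and the dose multiplier to reach 90%
PTA at a breakpoint is breakpoint / MIC90 by dose linearity. Default
1000 subjects per curve; the sampler is plain Monte Carlo by default, with
scrambled-Sobol and Latin-hypercube options that draw the same marginal
N(0, ω²) law with ~3× smaller Monte Carlo error — the acceptance script
uses Sobol so its reported values reflect the model rather than sampler
noise. Parameter uncertainty enters by re-running the PTA curve per
bootstrap parameter set and taking pointwise medians and 5th–95th bands.

## Synthetic cohorts

The generator reproduces the study design: 19 subjects, 1 g infused over
1 h every 8 h, samples at 0, 0.25, 0.5, 0.75, 1, 1.25, 1.5, 2, 3, 4 and
8 h after the start of the monitored infusion; 9 of 19 subjects sampled at
the first dose, the rest at steady state after 12 prior doses (96 h ≈ 27
typical terminal half-lives). Albumin is a Beta(2.5, 2.07) scaled to
[15.6, 31.8] g/l (median ≈ 24.6, matching the reported median/range — only
those two statistics are available); weight is uniform on [60, 100] kg;
age a scaled Beta(3, 1.3) on [36, 79] y (median ≈ 67); sepsis probability
falls logistically with albumin (50% at the median), mirroring the
observed albumin–sepsis confounding, and is used only as a candidate
covariate. Each cohort records its true etas and parameters for recovery
tests.

Two deliberate departures from the raw study data: (i) the study reports
256 observations from 19 patients versus the 209 scheduled samples — the
extra, unrecorded clinical samples are not emulated; (ii) clean time-zero
samples of first-dose subjects are stored flagged-excluded, because an
exact observed zero at an exact predicted zero makes the additive-error
likelihood unbounded (σ_add → 0) — they carry no information under the
model. An optional contamination rate inserts spurious predose-positive
records (uniform on [LLOQ, 2] mg/l) to exercise the exclusion rule.
Below-LLOQ (0.1 mg/l) observations are flagged and discarded from fitting.

What passing tests on these cohorts do not show: robustness to real-data
features the generator omits — dose deviations and recording errors,
within-day clearance changes from filter clotting/exchange, correlated
covariates beyond albumin–sepsis, and any model misspecification of the
two-compartment/log-normal/combined-error form itself.

## Problem sizes used in the tests

The test suite runs estimation checks at the scales a desk replication
supports: quadrature-oracle toys of 1–3 observations; parameter recovery
on one 50-subject cohort at the study sampling schedule (fixed-effect
scatter at this size is ±10–30% for the weakly identified V2-related
parameters, consistent with the wide V2 bootstrap interval reported for
the original 19-subject study, so the recovery tolerances are tight);
stepwise covariate selection at the 19-subject study design with 10 null
replicates; bootstrap calibration with 100 resamples of an 8-subject
cohort generated without covariate effects (a design where every typical
value is identified, so the median-versus-estimate comparison measures the
bootstrap rather than likelihood skewness); VPC coverage over 15 replicate
19-subject cohorts with 200 simulations each. PTA checks use 1000 subjects
per curve as in the original analysis.

## Known limitations

- The estimator is a conditional-mode approximation; its OFV differs from
  exact quadrature by up to ~0.05 on sparse single-eta problems (tested)
  and by an unquantified-but-similar amount in three eta dimensions.
- Off-diagonal Ω (correlated random effects) and inter-occasion
  variability are not supported; the source analysis reported neither.
- Below-LLOQ handling is the discard method only.
- One-compartment fits are supported for model comparison but report a
  placeholder disconnected peripheral compartment in the result container.
- PTA assumes perfect adherence to the nominal schedule and ignores
  residual assay error by design.
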