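# meropk

Population pharmacokinetics of standard-dose meropenem in critically ill
patients on continuous renal replacement therapy (CRRT), as a tested,
reusable Python pipeline: structural kinetics, nonlinear mixed-effects
estimation with covariate selection, bootstrap/VPC model evaluation, and
Monte Carlo probability-of-target-attainment (PTA) simulation for
%T>MIC dosing targets.

## Who this is for

Pharmacometricians and infectious-disease modellers who want to (i) apply
or re-estimate the published meropenem-CRRT population model, (ii) run
dosing simulations against %T>MIC targets for patients with different serum
albumin concentrations, or (iii) use the synthetic-cohort generator and
estimation machinery as a workbench for small-sample population-PK
methodology.

## The model

Plasma meropenem follows a two-compartment model with zero-order infusion
input and elimination exclusively by CRRT:

    V1 dC1/dt = -Q·C1 + Q·C2 - Cl_CRRT·C1 + R(t)
    V2 dC2/dt =  Q·C1 - Q·C2

Individual parameters are log-normal around covariate-adjusted typical
values, P_i = θ_P · f(COV_i) · exp(η_P,i) with η ~ N(0, ω²_P), and
observations carry combined additive + proportional residual error,
C_obs = C1·(1 + ε_prop) + ε_add.  The final covariate relationship is a
power law of serum albumin on the central volume:

    V1_i = 27.9 · (ALB_i / 24.6)^(-2.87) · exp(η_V1,i)   [l, ALB in g/l]

with θ_V2 = 33.7 l, θ_Cl,CRRT = 15.1 l/h, θ_Q = 21.1 l/h, IIV of
53.1 / 43.7 / 85.6 %CV on V1 / Cl / V2 (none on Q), σ_add = 0.881 mg/l and
σ_prop = 24.1%.  `meropk.meropenem_crrt_model()` returns this model.

Estimation uses an approximate marginal likelihood at the conditional mode
of the random effects with the residual variance evaluated at conditional
predictions (FOCE-with-interaction convention): adaptive Gauss–Hermite
quadrature for a single random effect, the Laplace value otherwise.
Covariate selection is stepwise: forward inclusion at ΔOFV ≥ 3.84
(χ², p < 0.05), backward elimination unless removal costs > 7.9 (p < 0.005).

PTA is computed by simulating virtual subjects from the population model
(no residual error), evaluating steady-state concentration profiles over
one dosing interval in closed form, and scoring the fraction of the
interval above MIC — 40% for the classical carbapenem target, 100% for
trough-above-MIC.  Dose linearity lets one 1000-mg PTA curve be re-indexed
to any dose via the factor fr = dose/1000.

## Worked example

```python
import numpy as np
from meropk import (meropenem_crrt_model, DosingRegimen, simulate_pta,
                    mic_at_pta, dose_multiplier)

model = meropenem_crrt_model()
regimen = DosingRegimen(dose=1000, tau=8, duration=1.0)  # 1 g q8h, 1-h infusion

for albumin in (15.6, 24.6, 31.8):   # lowest / median / highest observed
    res = simulate_pta(model, regimen, albumin=albumin, target_fraction=1.0,
                       n_subjects=1000, rng=np.random.default_rng(1),
                       sampler="sobol")
    mic90 = mic_at_pta(res, level=90.0)
    print(f"ALB {albumin:4.1f} g/l: PTA(2 mg/l) = {res.pta_at(2.0):5.1f}%, "
          f"MIC at 90% PTA = {mic90.mic:5.2f} mg/l, "
          f"dose multiplier to 90% PTA at 2 mg/l = {dose_multiplier(res):4.2f}")
```

prints

```
ALB 15.6 g/l: PTA(2 mg/l) =  89.7%, MIC at 90% PTA =  1.95 mg/l, dose multiplier to 90% PTA at 2 mg/l = 1.03
ALB 24.6 g/l: PTA(2 mg/l) =  65.9%, MIC at 90% PTA =  0.66 mg/l, dose multiplier to 90% PTA at 2 mg/l = 3.05
ALB 31.8 g/l: PTA(2 mg/l) =  54.6%, MIC at 90% PTA =  0.35 mg/l, dose multiplier to 90% PTA at 2 mg/l = 5.79
```

Reading: at the median albumin, keeping the steady-state trough above an
MIC of 2 mg/l (the usual Gram-negative breakpoint) succeeds in only about
two-thirds of patients with the standard dose; the whole-interval target is
reliably (90%) attained only up to an MIC of ~0.7 mg/l, and reaching 90%
attainment at 2 mg/l would require roughly a 3-fold higher dose.
Hypoalbuminaemic patients (15.6 g/l) have a much larger central volume,
longer effective half-life, and hence higher troughs and better target
attainment.

The same workflow is scriptable from the shell:

```bash
meropk simulate-cohort --seed 1 --out cohort.csv --truth truth.json
meropk fit --data cohort.csv --params params.json --report fit.json
meropk pta --seed 1 --albumin 24.6 --target 100 --out pta.csv --summary pta.json
```

## Layout

- `meropk.dataset` — event-record (NONMEM-style CSV) data model and I/O,
  below-LLOQ flagging, predose-outlier exclusion rule
- `meropk.structural` — closed-form two-compartment infusion kinetics,
  steady-state accumulation, ODE test oracle
- `meropk.popmodel` — fixed effects, covariate laws, log-normal IIV,
  residual error, the published final model
- `meropk.estimation` — conditional-mode marginal likelihood (OFV), fits,
  likelihood-ratio comparison, stepwise covariate search
- `meropk.diagnostics` — VPC, nonparametric bootstrap, IWRES/CWRES
- `meropk.pta` — %T>MIC, PTA curves, MIC-at-90%-PTA, dose scaling
- `meropk.cohort` — synthetic study cohorts with known ground truth
- `meropk.cli` — `meropk` command-line front end

See `docs/methods.md` for the modelling and numerical details.
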