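# foalpk

Population pharmacokinetics of intravenous ampicillin in neonatal foals:
a 2-compartment nonlinear mixed-effects model with age covariates and a
below-quantification-limit (BLQ) censored likelihood, SAEM estimation,
internal-validation diagnostics, and Monte Carlo probability-of-target-
attainment (PTA) simulations for dosing-regimen selection.

## Who this is for

Veterinary clinical pharmacologists and pharmacometricians who want to
(a) re-estimate or extend the foal ampicillin model on their own data,
(b) stress-test SAEM/diagnostic machinery on a realistic censored-data
design, or (c) run PTA simulations for time-dependent antibiotics where
the efficacy driver is fT>MIC — the fraction of the treatment window the
free drug concentration spends above the pathogen's MIC.

## The model

Disposition is a 2-compartment IV bolus model (Cl, V1, Q, V2; first-order
elimination).  Individual parameters are log-normal around covariate-
adjusted typical values, with age (hours, centered at the weighted cohort
mean 61.8 h) acting as a power of the ratio on clearance and peripheral
volume:

    log Cl_i = log Cl_pop + β_Cl·log(age_i/61.8) + η_Cl,i,   η ~ N(0, ω²)
    log V2_i = log V2_pop + β_V2·log(age_i/61.8) + η_V2,i

Residual error is combined additive + proportional,
`y = C_pred + (a + b·C_pred)·ε`; observations below the 0.3 mg/L assay
LLOQ contribute the interval probability P(0 ≤ y ≤ LLOQ) to the
likelihood.  The published estimates (Cl_pop 17.43 L/h, V1 18.83 L,
Q 16.79 L/h, V2 22.12 L fixed, β_Cl 0.40, β_V2 1.38, ω_Cl 0.55, ω_V1 0.32,
ω_Q 0.49 fixed, ω_V2 1.04, a 0.12 mg/L, b 0.40) ship as
`foalpk.reference_model()`.

PTA simulations draw virtual foals (parameter uncertainty from the
reported RSEs, between-subject variability, covariates from the cohort
distributions or from log-normal age scenarios), dose them on a
15–40 mg/kg × q4–q8h grid for 48 h, apply 15% protein binding, and report
the percentage attaining 50% fT>1×MIC, 100% fT>1×MIC or 50% fT>4×MIC;
PTA ≥ 90% marks a regimen optimal.

Raw study data are not public, so `foalpk.cohort` generates synthetic
study-like cohorts (12 foals, ages 9–194.5 h, median weight 48.5 kg,
median 13 samples/foal over 48 h, ~8% BLQ) anchored to the published
summary statistics — every estimation and diagnostic component is testable
without external data.

## Worked example

```
$ python examples/04_pta_dosing.py
PTA (%) by regimen x MIC, study population, 50% fT>MIC target:
mic                   0.06  0.25  0.50  2.00
dose_per_kg interval
15.0        4.0       99.5  98.1  94.9  78.5
            6.0       98.5  94.3  88.1  62.8
            8.0       96.7  89.8  81.8  49.1
20.0        4.0       99.6  98.7  96.4  83.1
            6.0       98.6  95.7  91.0  70.5
...
40.0        4.0       99.9  99.4  98.7  91.5

least-intensive regimen reaching PTA >= 90% per MIC:
 mic recommendation  pta
 0.1   15 mg/kg q8h 96.7
 0.2   20 mg/kg q8h 92.6
 0.5   20 mg/kg q6h 91.0
 2.0   40 mg/kg q4h 91.5
```

Reading: the standard 20 mg/kg q6h regimen keeps PTA at 91% for MICs up to
0.5 mg/L under the 50% fT>MIC target — covering all seven MICs measured in
the study's isolates (0.06–0.5 mg/L) — while an MIC of 2 mg/L requires
40 mg/kg every 4 h.  `examples/01–03` walk through profile simulation,
SAEM re-estimation of a synthetic cohort, and the pcVPC/NPDE/bootstrap
diagnostics the same way.

A thin CLI mirrors the stages (`foalpk simulate-cohort | fit | loglik |
diagnose | bootstrap | pta | report | run`); `foalpk run config.yaml`
executes a seeded, hash-logged fit → diagnostics → PTA pipeline.

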