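"""Simulate a study-like cohort and re-estimate the model by SAEM.

Draws a 12-foal synthetic cohort (ages 9-194.5 h, 20 mg/kg q6h, ~13 samples
per foal, 0.3 mg/L LLOQ) from the published model, fits the 2-compartment
age-covariate model with the interval-censored likelihood, and prints the
parameter table with RSEs from the score-based Fisher information.
"""

import numpy as np

from foalpk import CohortSpec, Regimen, generate_dataset, reference_model
from foalpk.estimation import ModelSpec, SaemSettings, saem_fit

np.seterr(all="ignore")

model = reference_model()
dataset = generate_dataset(CohortSpec(), model, Regimen(20.0, 6.0),
                           np.random.default_rng(123))
print(f"dataset: {dataset.n_subjects} foals, {dataset.n_observations} samples, "
      f"{dataset.n_censored} below the 0.3 mg/L LLOQ")

fit = saem_fit(dataset, ModelSpec.from_population_model(model),
               SaemSettings(seed=1))
print(fit.parameter_table().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"loglik {fit.loglik:.1f} (MC se {fit.loglik_se:.2f}), BICc {fit.bicc:.1f}, "
      f"converged: {fit.converged}")
print("eta-shrinkage:", {k: f"{v:.1%}" for k, v in fit.shrinkage.items()})
# Estimates land near the generating values (Cl_pop 17.43, V1_pop 18.83 ...);
# V2_pop and omega_Q stay frozen, mirroring the published model building.
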