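import numpy as np
import pytest

from foalpk import CohortSpec, Regimen, generate_dataset, reference_model
from foalpk.estimation import ModelSpec, SaemSettings, saem_fit

np.seterr(all="ignore")


@pytest.fixture(scope="session")
def table2_model():
    """The published final 2-compartment age-covariate model."""
    return reference_model()


@pytest.fixture(scope="session")
def foal_dataset(table2_model):
    """One synthetic 12-foal dataset simulated from the final model."""
    rng = np.random.default_rng(20260929)
    return generate_dataset(CohortSpec(), table2_model, Regimen(20.0, 6.0), rng)


@pytest.fixture(scope="session")
def fast_settings():
    """Reduced SAEM schedule for unit tests (no loglik / FIM side computations)."""
    return SaemSettings(
        seed=11,
        compute_loglik=False,
        compute_fim=False,
        ebe_samples=30,
        ebe_burnin=40,
    )


@pytest.fixture(scope="session")
def foal_fit(foal_dataset, table2_model, fast_settings):
    """A full-schedule SAEM fit of the synthetic cohort, shared across tests."""
    spec = ModelSpec.from_population_model(table2_model)
    return saem_fit(foal_dataset, spec, fast_settings)
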