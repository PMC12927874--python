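"""The population (mixed-effects) layer of the ampicillin model.

A subject's structural parameters are log-normally distributed around
covariate-adjusted typical values:

    log(theta_i) = log(theta_pop) + beta * log(cov_i / ref) + eta_i,
    eta_i ~ N(0, omega^2), independent across parameters (diagonal BSV).

The final foal model carries age (centered at 61.8 h, the weighted cohort
mean) on clearance and on the peripheral volume.  Residual variability is a
combined additive + proportional error; observations below the assay LLOQ
(0.3 mg/L) are interval-censored between 0 and the LLOQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .compartmental import DoseEvent, StructuralParams, concentration

__all__ = [
    "Covariates",
    "PopulationModel",
    "IndividualParams",
    "ObservationModel",
    "typical_params",
    "sample_individual",
    "residual_sd",
    "observation_loglik",
    "simulate_observations",
    "reference_model",
    "reference_rse",
    "AGE_REFERENCE_H",
    "DEFAULT_LLOQ",
]

#: Age-centering constant of the covariate model (hours).
AGE_REFERENCE_H = 61.8
#: Lower limit of quantification of the ampicillin assay (mg/L).
DEFAULT_LLOQ = 0.3

# SD floor applied defensively so the residual SD is never exactly zero.
_SD_FLOOR = 1e-10

_ERROR_KINDS = ("constant", "proportional", "combined1", "combined2")
_PARAM_NAMES = ("cl", "v1", "q", "v2")


@dataclass(frozen=True)
class Covariates:
    """Subject-level covariates: age (h), body weight (kg) and serum chemistry."""

    age: float
    tbw: float
    albumin: float | None = None
    creatinine: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0 h, got {self.age!r}")
        if self.tbw <= 0:
            raise ValueError(f"tbw must be > 0 kg, got {self.tbw!r}")


@dataclass(frozen=True)
class ObservationModel:
    """Residual-error model and assay censoring limit.

    ``kind`` selects among a constant SD (``a``), a proportional SD
    (``b * C``), their sum (``combined1``, the final foal model) or the
    root-sum-of-squares form (``combined2``).
    """

    kind: str = "combined1"
    a: float = 0.0
    b: float = 0.0
    lloq: float = DEFAULT_LLOQ

    def __post_init__(self) -> None:
        if self.kind not in _ERROR_KINDS:
            raise ValueError(f"unknown error model {self.kind!r}; expected one of {_ERROR_KINDS}")
        if self.a < 0 or self.b < 0:
            raise ValueError("error constants a, b must be >= 0")
        # a == b == 0 is allowed for noise-free simulation; the residual SD is
        # floored at a tiny positive value wherever a likelihood is evaluated


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, covariate coefficients, BSV SDs and residual error.

    ``fixed`` lists parameter names that were frozen (not estimated) during
    model building; it has no effect on simulation, only on how estimation
    and reporting treat the parameter.
    """

    cl_pop: float
    v1_pop: float
    q_pop: float
    v2_pop: float
    beta_cl_logage: float = 0.0
    beta_v2_logage: float = 0.0
    omega_cl: float = 0.0
    omega_v1: float = 0.0
    omega_q: float = 0.0
    omega_v2: float = 0.0
    err_a: float = 0.0
    err_b: float = 0.0
    error_kind: str = "combined1"
    lloq: float = DEFAULT_LLOQ
    age_ref: float = AGE_REFERENCE_H
    fixed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for name in ("cl_pop", "v1_pop", "q_pop", "v2_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_cl", "omega_v1", "omega_q", "omega_v2", "err_a", "err_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.err_a == 0 and self.err_b == 0 and self.error_kind != "constant":
            # a completely noise-free model is allowed only for deterministic
            # simulation; ObservationModel construction below will enforce
            # positivity where a likelihood is actually evaluated.
            pass
        if self.age_ref <= 0:
            raise ValueError("age_ref must be > 0")

    @property
    def observation_model(self) -> ObservationModel:
        return ObservationModel(self.error_kind, self.err_a, self.err_b, self.lloq)

    def omegas(self) -> dict[str, float]:
        return {
            "cl": self.omega_cl,
            "v1": self.omega_v1,
            "q": self.omega_q,
            "v2": self.omega_v2,
        }

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class IndividualParams:
    """One subject's realised structural parameters and their random effects."""

    structural: StructuralParams
    etas: dict[str, float] = field(default_factory=dict)


def typical_params(model: PopulationModel, cov: Covariates) -> StructuralParams:
    """Covariate-adjusted typical values (all etas zero).

    Age acts as a power of the ratio ``age / age_ref`` on clearance and
    peripheral volume; at ``age == age_ref`` the typical values equal the
    population values exactly.
    """
    ratio = cov.age / model.age_ref
    cl = model.cl_pop * ratio**model.beta_cl_logage
    v2 = model.v2_pop * ratio**model.beta_v2_logage
    return StructuralParams(cl=cl, v1=model.v1_pop, q=model.q_pop, v2=v2)


def sample_individual(
    model: PopulationModel, cov: Covariates, rng: np.random.Generator
) -> IndividualParams:
    """Draw one subject: ``theta_i = typical(cov) * exp(N(0, omega^2))`` per parameter."""
    tv = typical_params(model, cov)
    om = model.omegas()
    etas = {p: (rng.normal(0.0, om[p]) if om[p] > 0 else 0.0) for p in _PARAM_NAMES}
    structural = StructuralParams(
        cl=tv.cl * np.exp(etas["cl"]),
        v1=tv.v1 * np.exp(etas["v1"]),
        q=tv.q * np.exp(etas["q"]),
        v2=tv.v2 * np.exp(etas["v2"]),
    )
    return IndividualParams(structural=structural, etas=etas)


def residual_sd(obs_model: ObservationModel, c_pred: np.ndarray | float) -> np.ndarray | float:
    """Residual-error SD at the predicted concentration (mg/L)."""
    c = np.asarray(c_pred, dtype=float)
    if np.any(c < 0):
        raise ValueError("c_pred must be >= 0")
    if obs_model.kind == "constant":
        sd = np.full_like(c, obs_model.a)
    elif obs_model.kind == "proportional":
        sd = obs_model.b * c
    elif obs_model.kind == "combined1":
        sd = obs_model.a + obs_model.b * c
    else:  # combined2
        sd = np.sqrt(obs_model.a**2 + obs_model.b**2 * c**2)
    sd = np.maximum(sd, _SD_FLOOR)
    if np.isscalar(c_pred):
        return float(sd)
    return sd


def observation_loglik(
    obs_model: ObservationModel,
    c_pred: np.ndarray | float,
    y_obs: np.ndarray | float,
    censored: np.ndarray | bool = False,
) -> np.ndarray | float:
    """Log-density of one or more observations given the model prediction.

    Uncensored rows contribute a Normal log-density; censored rows (below
    the LLOQ) contribute the interval probability that the latent
    concentration lies between 0 and the LLOQ:
    ``log[ Phi((lloq - c)/sd) - Phi((0 - c)/sd) ]``.
    """
    c = np.atleast_1d(np.asarray(c_pred, dtype=float))
    y = np.atleast_1d(np.asarray(y_obs, dtype=float))
    cen = np.broadcast_to(np.atleast_1d(np.asarray(censored, dtype=bool)), y.shape)
    sd = np.atleast_1d(np.asarray(residual_sd(obs_model, c), dtype=float))
    out = np.empty_like(y)
    unc = ~cen
    if np.any(unc):
        out[unc] = stats.norm.logpdf(y[unc], loc=c[unc], scale=sd[unc])
    if np.any(cen):
        hi = stats.norm.logcdf((obs_model.lloq - c[cen]) / sd[cen])
        lo = stats.norm.logcdf((0.0 - c[cen]) / sd[cen])
        # log(exp(hi) - exp(lo)) computed stably; lo <= hi always
        with np.errstate(divide="ignore", invalid="ignore"):
            out[cen] = hi + np.log1p(-np.exp(np.minimum(lo - hi, 0.0)))
        out[cen] = np.where(np.isnan(out[cen]), -np.inf, out[cen])
    if np.isscalar(y_obs) or np.asarray(y_obs).ndim == 0:
        return float(out[0])
    return out


def simulate_observations(
    model: PopulationModel,
    individual: IndividualParams,
    doses: list[DoseEvent],
    sample_times: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate assay observations for one subject, applying LLOQ censoring.

    Returns a tidy frame (time, c_pred, dv, cens, lloq).  A draw that falls
    below the LLOQ — including any negative draw — is emitted as a censored
    row (``cens = 1``) with ``dv`` set to NaN and the LLOQ recorded,
    mirroring how a quantification-limited assay reports such samples.
    """
    t = np.asarray(sample_times, dtype=float)
    c_pred = concentration(individual.structural, doses, t)
    obs = model.observation_model
    sd = np.asarray(residual_sd(obs, c_pred), dtype=float)
    y = c_pred + sd * rng.standard_normal(t.shape)
    cens = y < model.lloq
    return pd.DataFrame(
        {
            "time": t,
            "c_pred": c_pred,
            "dv": np.where(cens, np.nan, y),
            "cens": cens.astype(int),
            "lloq": model.lloq,
        }
    )


def reference_model() -> PopulationModel:
    """Final published population estimates for IV ampicillin in neonatal foals.

    Two-compartment disposition; age (h, centered at 61.8) on clearance and
    peripheral volume; diagonal log-normal BSV; combined additive +
    proportional residual error.  ``v2_pop`` and ``omega_q`` were frozen in
    the final estimation step.
    """
    return PopulationModel(
        cl_pop=17.43,
        v1_pop=18.83,
        q_pop=16.79,
        v2_pop=22.12,
        beta_cl_logage=0.40,
        beta_v2_logage=1.38,
        omega_cl=0.55,
        omega_v1=0.32,
        omega_q=0.49,
        omega_v2=1.04,
        err_a=0.12,
        err_b=0.40,
        error_kind="combined1",
        lloq=DEFAULT_LLOQ,
        age_ref=AGE_REFERENCE_H,
        fixed=frozenset({"v2_pop", "omega_q"}),
    )


def reference_rse() -> dict[str, float]:
    """Relative standard errors (%) of the published estimates (fixed params absent)."""
    return {
        "cl_pop": 17.74,
        "beta_cl_logage": 39.19,
        "v1_pop": 11.21,
        "q_pop": 32.31,
        "beta_v2_logage": 44.8,
        "omega_cl": 25.18,
        "omega_v1": 32.50,
        "omega_v2": 39.53,
        "err_a": 36.18,
        "err_b": 8.30,
    }
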