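"""SAEM estimation of the population model from censored longitudinal data.

Maximum-likelihood estimation by stochastic approximation EM: the E-step
samples each subject's log-scale random effects (and, for observations
below the LLOQ, the latent concentration inside [0, LLOQ]) by
Metropolis-within-Gibbs; the M-step updates population coefficients and
variances from stochastically-averaged sufficient statistics.  Positive
parameters are estimated on the log scale, covariate coefficients on the
identity scale.

Companion operations: importance-sampling marginal log-likelihood, the
corrected BIC with separate subject-level and observation-level penalties,
Wald tests for covariate coefficients, empirical Bayes (conditional)
estimates, eta-shrinkage, and a one-at-a-time covariate selection loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy import optimize, stats

from .dataset import PKDataset
from .popmodel import DEFAULT_LLOQ, PopulationModel

__all__ = [
    "CovariateTerm",
    "ParameterSpec",
    "ModelSpec",
    "SaemSettings",
    "FitResult",
    "saem_fit",
    "loglik_importance_sampling",
    "bicc",
    "wald_test",
    "ebe_conditional",
    "shrinkage",
    "covariate_selection",
    "naive_two_stage_init",
]

_LOG_2PI = math.log(2.0 * math.pi)


def _safe_exp(x: np.ndarray) -> np.ndarray:
    """exp with the argument clipped to avoid overflow in degenerate states."""
    return np.exp(np.clip(x, -30.0, 30.0))


_STRUCTURAL_NAMES = {1: ("cl", "v1"), 2: ("cl", "v1", "q", "v2"), 3: ("cl", "v1", "q", "v2", "q3", "v3")}


@dataclass(frozen=True)
class CovariateTerm:
    """A log-ratio covariate effect: ``beta * log(cov / reference)`` on log-theta."""

    covariate: str
    reference: float
    init: float = 0.0
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError("covariate reference must be > 0")


@dataclass(frozen=True)
class ParameterSpec:
    """One structural parameter: initial typical value, BSV, covariate terms."""

    name: str
    init: float
    fixed: bool = False
    omega_init: float = 0.3
    omega_fixed: bool = False
    covariates: tuple[CovariateTerm, ...] = ()

    def __post_init__(self) -> None:
        if self.init <= 0:
            raise ValueError(f"init for {self.name} must be > 0")
        if self.omega_init <= 0:
            raise ValueError(
                f"omega_init for {self.name} must be > 0 (a parameter without "
                "between-subject variability is not estimable by this sampler; "
                "fix a small omega instead)"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Structural + statistical model specification for estimation."""

    params: tuple[ParameterSpec, ...]
    error_kind: str = "combined1"
    err_a_init: float = 0.5
    err_b_init: float = 0.3
    err_fixed: bool = False
    lloq: float = DEFAULT_LLOQ
    n_compartments: int = 2

    def __post_init__(self) -> None:
        expected = _STRUCTURAL_NAMES.get(self.n_compartments)
        if expected is None:
            raise ValueError("n_compartments must be 1, 2 or 3")
        names = tuple(p.name for p in self.params)
        if names != expected:
            raise ValueError(f"params must be {expected} in order for {self.n_compartments}-compartment model")
        if self.error_kind not in ("constant", "proportional", "combined1", "combined2"):
            raise ValueError(f"unknown error kind {self.error_kind!r}")

    @classmethod
    def two_compartment(
        cls,
        inits: dict[str, float] | None = None,
        age_on_cl: bool = True,
        age_on_v2: bool = True,
        age_ref: float = 61.8,
        fix_v2: bool = False,
        fix_omega_q: bool = False,
        omega_inits: dict[str, float] | None = None,
        beta_inits: dict[str, float] | None = None,
        **kwargs,
    ) -> "ModelSpec":
        """The foal ampicillin model structure: 2 compartments, age on Cl and V2."""
        inits = {"cl": 15.0, "v1": 20.0, "q": 15.0, "v2": 25.0, **(inits or {})}
        om = {"cl": 0.4, "v1": 0.3, "q": 0.4, "v2": 0.6, **(omega_inits or {})}
        be = {"cl": 0.0, "v2": 0.0, **(beta_inits or {})}
        mk = lambda n, fixed=False, ofix=False, covs=(): ParameterSpec(
            n, inits[n], fixed=fixed, omega_init=om[n], omega_fixed=ofix, covariates=covs
        )
        params = (
            mk("cl", covs=(CovariateTerm("age", age_ref, init=be["cl"]),) if age_on_cl else ()),
            mk("v1"),
            mk("q", ofix=fix_omega_q),
            mk("v2", fixed=fix_v2, covs=(CovariateTerm("age", age_ref, init=be["v2"]),) if age_on_v2 else ()),
        )
        return cls(params=params, n_compartments=2, **kwargs)

    @classmethod
    def one_compartment(cls, inits: dict[str, float] | None = None, **kwargs) -> "ModelSpec":
        inits = {"cl": 15.0, "v1": 25.0, **(inits or {})}
        params = (
            ParameterSpec("cl", inits["cl"], omega_init=0.4),
            ParameterSpec("v1", inits["v1"], omega_init=0.4),
        )
        return cls(params=params, n_compartments=1, **kwargs)

    @classmethod
    def from_population_model(cls, model: PopulationModel) -> "ModelSpec":
        """Spec initialised at (and fixed like) a published 2-compartment model."""
        return cls.two_compartment(
            inits={"cl": model.cl_pop, "v1": model.v1_pop, "q": model.q_pop, "v2": model.v2_pop},
            omega_inits={
                "cl": model.omega_cl, "v1": model.omega_v1,
                "q": model.omega_q, "v2": model.omega_v2,
            },
            beta_inits={"cl": model.beta_cl_logage, "v2": model.beta_v2_logage},
            age_on_cl=model.beta_cl_logage != 0.0,
            age_on_v2=model.beta_v2_logage != 0.0,
            age_ref=model.age_ref,
            fix_v2="v2_pop" in model.fixed,
            fix_omega_q="omega_q" in model.fixed,
            error_kind=model.error_kind,
            err_a_init=max(model.err_a, 1e-3),
            err_b_init=max(model.err_b, 1e-3),
            lloq=model.lloq,
        )

    def n_subject_level_params(self) -> int:
        """Free fixed effects + covariate betas + omegas (BICc subject penalty)."""
        n = 0
        for p in self.params:
            n += (not p.fixed) + sum(not t.fixed for t in p.covariates) + (not p.omega_fixed)
        return n

    def n_obs_level_params(self) -> int:
        """Free residual-error constants (BICc observation penalty)."""
        if self.err_fixed:
            return 0
        return {"constant": 1, "proportional": 1}.get(self.error_kind, 2)


@dataclass(frozen=True)
class SaemSettings:
    """SAEM schedule and Monte Carlo sizes.

    Defaults: 2 chains, 300 exploratory iterations (step size 1, simulated
    annealing on the variance parameters), 150 smoothing iterations with
    step size ``1/k**step_exponent``, and per transition 2 component-wise
    random-walk kernels plus 1 joint kernel.
    """

    n_chains: int = 2
    n_burnin: int = 300
    n_smoothing: int = 150
    n_componentwise_kernels: int = 2
    n_joint_kernels: int = 1
    step_exponent: float = 0.7
    seed: int = 12345
    loglik_is_samples: int = 10000
    compute_loglik: bool = True
    compute_fim: bool = True
    ebe_samples: int = 200
    ebe_burnin: int = 100
    annealing: float = 0.95
    adapt_rate: float = 0.05
    target_accept: float = 0.35

    def __post_init__(self) -> None:
        if self.n_burnin < 1 or self.n_smoothing < 1 or self.n_chains < 1:
            raise ValueError("iteration and chain counts must be >= 1")
        if not (0.5 < self.step_exponent <= 1.0):
            raise ValueError("step_exponent must lie in (0.5, 1]")


# ---------------------------------------------------------------------------
# internal problem representation (padded arrays, chain-stacked)


class _Problem:
    def __init__(self, dataset: PKDataset, spec: ModelSpec):
        subs = list(dataset.subjects())
        self.subject_ids = [s.subject_id for s in subs]
        self.n_sub = len(subs)
        self.spec = spec
        self.P = len(spec.params)
        J = max(len(s.obs_times) for s in subs)
        D = max(len(s.doses) for s in subs)
        n = self.n_sub
        self.y = np.zeros((n, J))
        self.cens = np.zeros((n, J), bool)
        self.omask = np.zeros((n, J), bool)
        self.DT = np.zeros((n, J, D))
        self.dmask = np.zeros((n, J, D))
        self.AMT = np.zeros((n, D))
        for i, s in enumerate(subs):
            j = len(s.obs_times)
            if j < 2:
                raise ValueError(f"subject {s.subject_id!r} has fewer than 2 observations")
            self.omask[i, :j] = True
            self.cens[i, :j] = s.cens
            self.y[i, :j] = np.where(s.cens, 0.0, np.nan_to_num(s.dv))
            for d, ev in enumerate(s.doses):
                self.AMT[i, d] = ev.amount
                dt = s.obs_times - ev.time
                self.DT[i, :j, d] = np.clip(dt, 0.0, None)
                self.dmask[i, :j, d] = dt >= 0
        self.n_obs_total = int(self.omask.sum())
        # per-parameter covariate design matrices (intercept + log-ratio terms)
        self.X: list[np.ndarray] = []
        for p in spec.params:
            cols = [np.ones(n)]
            for term in p.covariates:
                vals = []
                for s in subs:
                    v = getattr(s.covariates, term.covariate, None)
                    if v is None or not np.isfinite(v):
                        raise ValueError(
                            f"covariate {term.covariate!r} required on parameter {p.name!r} "
                            f"is missing for subject {s.subject_id!r}"
                        )
                    vals.append(math.log(v / term.reference))
                cols.append(np.asarray(vals))
            self.X.append(np.column_stack(cols))
        self.lloq = spec.lloq

    def stacked(self, n_chains: int) -> "_Problem":
        """A view with every subject replicated once per chain (row-stacked)."""
        if n_chains == 1:
            return self
        import copy

        p = copy.copy(self)
        reps = lambda a: np.concatenate([a] * n_chains, axis=0)
        for name in ("y", "cens", "omask", "DT", "dmask", "AMT"):
            setattr(p, name, reps(getattr(self, name)))
        p.X = [reps(x) for x in self.X]
        return p

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    def linear_predictor(self, coefs: list[np.ndarray]) -> np.ndarray:
        """(rows, P) matrix of covariate-adjusted log typical values."""
        return np.column_stack([self.X[p] @ coefs[p] for p in range(self.P)])

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Concentrations (rows, J) at the observation times from structural params.

        ``theta`` holds natural-scale values, columns ordered as spec.params.
        """
        nc = self.spec.n_compartments
        if nc == 1:
            cl, v1 = theta[:, 0], theta[:, 1]
            k10 = cl / v1
            E = np.exp(-k10[:, None, None] * self.DT) * self.dmask
            return np.einsum("rjd,rd->rj", E, self.AMT) / v1[:, None]
        if nc == 2:
            cl, v1, q, v2 = theta.T
            k10, k12, k21 = cl / v1, q / v1, q / v2
            s = k10 + k12 + k21
            pr = k10 * k21
            alpha = 0.5 * (s + np.sqrt(np.maximum(s * s - 4.0 * pr, 0.0)))
            beta = pr / alpha
            denom = np.maximum(v1 * (alpha - beta), 1e-300)
            ca = (alpha - k21) / denom
            cb = (k21 - beta) / denom
            E = (
                ca[:, None, None] * np.exp(-alpha[:, None, None] * self.DT)
                + cb[:, None, None] * np.exp(-beta[:, None, None] * self.DT)
            ) * self.dmask
            return np.einsum("rjd,rd->rj", E, self.AMT)
        # 3-compartment: eigendecomposition of the rate matrix, row by row
        out = np.zeros(self.y.shape)
        for r in range(self.n_rows):
            cl, v1, q2, v2, q3, v3 = theta[r]
            K = np.array(
                [
                    [-(cl + q2 + q3) / v1, q2 / v2, q3 / v3],
                    [q2 / v1, -q2 / v2, 0.0],
                    [q3 / v1, 0.0, -q3 / v3],
                ]
            )
            w, V = np.linalg.eig(K)
            coef = V[0, :] * np.linalg.solve(V, np.array([1.0, 0.0, 0.0]))
            E = np.real(np.exp(self.DT[r][:, :, None] * w[None, None, :]) @ coef) * self.dmask[r]
            out[r] = (E * self.AMT[r][None, :]).sum(axis=1) / v1
        return out

    def residual_sd(self, conc: np.ndarray, a: float, b: float) -> np.ndarray:
        kind = self.spec.error_kind
        if kind == "constant":
            sd = np.full_like(conc, a)
        elif kind == "proportional":
            sd = b * conc
        elif kind == "combined1":
            sd = a + b * conc
        else:
            sd = np.sqrt(a * a + b * b * conc * conc)
        return np.maximum(sd, 1e-10)

    def obs_loglik(self, theta: np.ndarray, a: float, b: float) -> np.ndarray:
        """(rows,) observation log-likelihood; censored rows use the [0, LLOQ]
        interval probability."""
        conc = self.predict(theta)
        sd = self.residual_sd(conc, a, b)
        z = (self.y - conc) / sd
        ll = -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI
        if self.cens.any():
            u1 = (self.lloq - conc) / sd
            u0 = -conc / sd
            p = np.maximum(ndtr(u1) - ndtr(u0), 1e-300)
            ll = np.where(self.cens, np.log(p), ll)
        return np.where(self.omask, ll, 0.0).sum(axis=1)


def _solve_coefs(
    A: np.ndarray, B: np.ndarray, current: np.ndarray, free: np.ndarray
) -> np.ndarray:
    """Constrained least-squares coefficient update (fixed entries kept)."""
    if not free.any():
        return current
    out = current.copy()
    Af = A[np.ix_(free, free)]
    rhs = B[free] - A[np.ix_(free, ~free)] @ current[~free]
    out[free] = np.linalg.solve(Af, rhs)
    return out


def _update_error(
    kind: str, a: float, b: float, f: np.ndarray, e: np.ndarray
) -> tuple[float, float]:
    """Complete-data ML update of the residual-error constants.

    ``f`` are model predictions, ``e`` the residuals (latent values sampled
    for censored rows).  Constant/proportional have closed forms; combined
    forms use a few damped Newton steps warm-started at the current values.
    """
    if kind == "constant":
        return float(np.sqrt(np.mean(e * e))), b
    if kind == "proportional":
        fp = np.maximum(f, 1e-10)
        return a, float(np.sqrt(np.mean((e / fp) ** 2)))
    if kind == "combined2":
        def negll(x):
            aa, bb = np.exp(x)
            sd = np.sqrt(aa * aa + bb * bb * f * f) + 1e-12
            return float(np.sum(np.log(sd) + 0.5 * (e / sd) ** 2))

        res = optimize.minimize(negll, np.log([max(a, 1e-4), max(b, 1e-4)]),
                                method="Nelder-Mead", options={"maxiter": 80, "xatol": 1e-4, "fatol": 1e-6})
        aa, bb = np.exp(res.x)
        return float(aa), float(bb)
    # combined1: sd = a + b f
    aa, bb = max(a, 1e-6), max(b, 1e-6)

    def negll1(aa_, bb_):
        sd = np.maximum(aa_ + bb_ * f, 1e-10)
        return float(np.sum(np.log(sd) + 0.5 * (e / sd) ** 2))

    cur = negll1(aa, bb)
    for _ in range(6):
        sd = np.maximum(aa + bb * f, 1e-10)
        s1 = 1.0 / sd - e * e / sd**3  # d negll / d sd
        s2 = -1.0 / sd**2 + 3.0 * e * e / sd**4
        g = np.array([np.sum(s1), np.sum(s1 * f)])
        H = np.array(
            [[np.sum(s2), np.sum(s2 * f)], [np.sum(s2 * f), np.sum(s2 * f * f)]]
        )
        # damp to keep H positive definite
        lam = 1e-8
        try:
            step = np.linalg.solve(H + lam * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(8):
            na, nb = aa - scale * step[0], bb - scale * step[1]
            if na > 1e-8 and nb > 1e-8:
                new = negll1(na, nb)
                if new <= cur + 1e-12:
                    aa, bb, cur = na, nb, new
                    break
            scale *= 0.5
        else:
            break
        if np.abs(step).max() * scale < 1e-8:
            break
    return float(aa), float(bb)


def _sample_censored_latents(
    prob: _Problem, conc: np.ndarray, a: float, b: float, rng: np.random.Generator
) -> np.ndarray:
    """Latent concentrations for censored rows, drawn from the truncated
    Normal on [0, LLOQ] given the current predictions."""
    sd = prob.residual_sd(conc, a, b)
    u0 = ndtr(-conc / sd)
    u1 = ndtr((prob.lloq - conc) / sd)
    u = u0 + (u1 - u0) * rng.uniform(size=conc.shape)
    return conc + sd * ndtri(np.clip(u, 1e-13, 1.0 - 1e-13))


@dataclass
class FitResult:
    """SAEM fit: estimates, uncertainty, likelihood, EBEs, diagnostics."""

    spec: ModelSpec
    settings: SaemSettings
    estimates: dict[str, float]
    se: dict[str, float]
    rse: dict[str, float]
    fim: np.ndarray | None
    fim_coords: tuple[str, ...]
    loglik: float | None
    loglik_se: float | None
    bicc: float | None
    ebe_eta: np.ndarray  # (n_sub, P) conditional means
    ebe_map: np.ndarray  # (n_sub, P) conditional modes
    ebe_samples: np.ndarray  # (S, n_sub, P) conditional-distribution samples
    shrinkage: dict[str, float]
    trace: pd.DataFrame
    converged: bool
    drift: dict[str, float]
    warnings: list[str]
    n_subjects: int
    n_observations: int
    _problem: _Problem = field(repr=False, default=None)
    _coefs: list[np.ndarray] = field(repr=False, default=None)
    _omega: np.ndarray = field(repr=False, default=None)
    _err: tuple[float, float] = field(repr=False, default=None)

    def omega_estimates(self) -> dict[str, float]:
        return {f"omega_{p.name}": self.estimates[f"omega_{p.name}"] for p in self.spec.params}

    def to_population_model(self) -> PopulationModel:
        """Convert to a simulation-ready model (2-compartment, age covariates)."""
        if self.spec.n_compartments != 2:
            raise ValueError("only the 2-compartment structure maps onto PopulationModel")
        est = self.estimates
        fixed = set()
        for p in self.spec.params:
            if p.fixed:
                fixed.add(f"{p.name}_pop")
            if p.omega_fixed:
                fixed.add(f"omega_{p.name}")
        age_ref = 61.8
        for p in self.spec.params:
            for t in p.covariates:
                if t.covariate != "age":
                    raise ValueError("PopulationModel supports only the age covariate")
                age_ref = t.reference
        return PopulationModel(
            cl_pop=est["cl_pop"],
            v1_pop=est["v1_pop"],
            q_pop=est["q_pop"],
            v2_pop=est["v2_pop"],
            beta_cl_logage=est.get("beta_cl_logage", 0.0),
            beta_v2_logage=est.get("beta_v2_logage", 0.0),
            omega_cl=est["omega_cl"],
            omega_v1=est["omega_v1"],
            omega_q=est["omega_q"],
            omega_v2=est["omega_v2"],
            err_a=est.get("err_a", 0.0),
            err_b=est.get("err_b", 0.0),
            error_kind=self.spec.error_kind,
            lloq=self.spec.lloq,
            age_ref=age_ref,
            fixed=frozenset(fixed),
        )

    def parameter_table(self) -> pd.DataFrame:
        """Tidy estimate / RSE% / 95% CI / fixed-flag table."""
        rows = []
        for name, val in self.estimates.items():
            se = self.se.get(name)
            if se is not None and name.startswith("beta"):
                lo, hi = val - 1.96 * se, val + 1.96 * se
            elif se is not None:
                # log-scale CI mapped to the natural scale
                sl = se / val if val > 0 else np.nan
                if np.isfinite(sl) and sl < 20.0:
                    lo, hi = val * math.exp(-1.96 * sl), val * math.exp(1.96 * sl)
                else:
                    lo, hi = np.nan, np.nan
            else:
                lo = hi = np.nan
            rows.append(
                {
                    "parameter": name,
                    "estimate": val,
                    "rse_pct": self.rse.get(name, np.nan),
                    "ci95_lo": lo,
                    "ci95_hi": hi,
                    "fixed": name not in self.rse,
                }
            )
        return pd.DataFrame(rows)


def _estimates_dict(spec: ModelSpec, coefs, omega, err) -> dict[str, float]:
    est: dict[str, float] = {}
    for p_idx, p in enumerate(spec.params):
        est[f"{p.name}_pop"] = float(np.exp(coefs[p_idx][0]))
        for t_idx, t in enumerate(p.covariates):
            est[f"beta_{p.name}_log{t.covariate}"] = float(coefs[p_idx][1 + t_idx])
        est[f"omega_{p.name}"] = float(omega[p_idx])
    kind = spec.error_kind
    if kind in ("constant", "combined1", "combined2"):
        est["err_a"] = float(err[0])
    if kind in ("proportional", "combined1", "combined2"):
        est["err_b"] = float(err[1])
    return est


def saem_fit(
    dataset: PKDataset,
    spec: ModelSpec | None = None,
    settings: SaemSettings | None = None,
) -> FitResult:
    """Fit the population model to a (possibly censored) dataset by SAEM.

    Deterministic given ``settings.seed``.  Raises on datasets with fewer
    than 2 subjects or subjects with fewer than 2 observations; flags (but
    does not hide) non-convergence and collapsing omegas in
    ``FitResult.warnings``.
    """
    if spec is None:
        spec = ModelSpec.two_compartment()
    if settings is None:
        settings = SaemSettings()
    base = _Problem(dataset, spec)
    if base.n_sub < 2:
        raise ValueError("SAEM needs at least 2 subjects")
    prob = base.stacked(settings.n_chains)
    rng = np.random.default_rng(settings.seed)
    P, R = base.P, prob.n_rows

    coefs = [
        np.concatenate([[math.log(p.init)], [t.init for t in p.covariates]])
        for p in spec.params
    ]
    free = [
        np.array([not p.fixed] + [not t.fixed for t in p.covariates])
        for p in spec.params
    ]
    omega = np.array([p.omega_init for p in spec.params])
    omega_free = np.array([not p.omega_fixed for p in spec.params])
    a, b = spec.err_a_init, spec.err_b_init

    # numerical guard rails: variance parameters may grow only gradually
    # during the exploratory phase (breaking the runaway feedback between a
    # flat likelihood and inflating variances) and are capped at generous
    # physical bounds (additive error bounded by the data spread).
    y_scale = float(np.std(prob.y[prob.omask & ~prob.cens])) if (prob.omask & ~prob.cens).any() else 1.0
    a_max = max(2.0 * y_scale, 10.0 * spec.err_a_init)
    b_max = 5.0
    omega_max = 4.0
    growth = 1.15

    # precomputed regression normal matrices (per parameter)
    A_mats = [x.T @ x / settings.n_chains for x in prob.X]

    eta = rng.normal(0.0, 0.2, size=(R, P)) * omega[None, :]
    # random-walk scales track the prior scale of each random effect
    scales = np.tile(np.maximum(0.8 * omega, 1e-8), (R, 1))
    joint_scale = np.full(R, 0.4)

    # SA accumulators
    B_stats = [np.zeros(len(c)) for c in coefs]
    S2_stats = np.zeros(P)
    init_stats = False

    n_iter = settings.n_burnin + settings.n_smoothing
    trace_rows = []
    err_ab = (a, b)

    def mcmc_sweep(eta, adapt):
        nonlocal scales, joint_scale
        mpred = prob.linear_predictor(coefs)
        ll = prob.obs_loglik(_safe_exp(mpred + eta), *err_ab)
        inv2o2 = 1.0 / (2.0 * omega**2)
        for _ in range(settings.n_componentwise_kernels):
            for p_ in range(P):
                prop = np.clip(eta[:, p_] + scales[:, p_] * rng.standard_normal(R), -20.0, 20.0)
                eta_new = eta.copy()
                eta_new[:, p_] = prop
                ll_new = prob.obs_loglik(_safe_exp(mpred + eta_new), *err_ab)
                dlog = ll_new - ll - inv2o2[p_] * (prop**2 - eta[:, p_] ** 2)
                acc = np.log(rng.uniform(size=R)) < np.nan_to_num(dlog, nan=-np.inf)
                eta[acc, p_] = prop[acc]
                ll = np.where(acc, ll_new, ll)
                if adapt:
                    scales[:, p_] *= np.exp(settings.adapt_rate * (acc - settings.target_accept))
        for _ in range(settings.n_joint_kernels):
            step = joint_scale[:, None] * scales * rng.standard_normal((R, P))
            eta_new = np.clip(eta + step, -20.0, 20.0)
            ll_new = prob.obs_loglik(_safe_exp(mpred + eta_new), *err_ab)
            dlog = ll_new - ll - (inv2o2[None, :] * (eta_new**2 - eta**2)).sum(axis=1)
            acc = np.log(rng.uniform(size=R)) < np.nan_to_num(dlog, nan=-np.inf)
            eta[acc] = eta_new[acc]
            ll = np.where(acc, ll_new, ll)
            if adapt:
                joint_scale *= np.exp(settings.adapt_rate * (acc - settings.target_accept))
        return eta

    for it in range(n_iter):
        burn = it < settings.n_burnin
        eta = mcmc_sweep(eta, adapt=burn)
        gamma = 1.0 if burn else (it - settings.n_burnin + 1) ** (-settings.step_exponent)

        mpred = prob.linear_predictor(coefs)
        phi = mpred + eta
        # sufficient statistics (averaged over chains)
        for p_ in range(P):
            b_stat = prob.X[p_].T @ phi[:, p_] / settings.n_chains
            B_stats[p_] = b_stat if not init_stats else B_stats[p_] + gamma * (b_stat - B_stats[p_])
        s2 = (phi**2).sum(axis=0) / settings.n_chains
        S2_stats = s2 if not init_stats else S2_stats + gamma * (s2 - S2_stats)
        init_stats = True

        new_omega2 = omega**2
        for p_ in range(P):
            coefs[p_] = _solve_coefs(A_mats[p_], B_stats[p_], coefs[p_], free[p_])
            if omega_free[p_]:
                c = coefs[p_]
                o2 = (S2_stats[p_] - 2.0 * c @ B_stats[p_] + c @ A_mats[p_] @ c) / base.n_sub
                o2 = max(o2, 1e-8)
                if burn:
                    o2 = max(o2, settings.annealing * omega[p_] ** 2)
                    o2 = min(o2, (growth * omega[p_]) ** 2)
                else:
                    o2 = omega[p_] ** 2 + gamma * (o2 - omega[p_] ** 2)
                new_omega2[p_] = min(o2, omega_max**2)
        omega = np.sqrt(new_omega2)

        if not spec.err_fixed:
            conc = prob.predict(_safe_exp(prob.linear_predictor(coefs) + eta))
            y_complete = prob.y
            if prob.cens.any():
                lat = _sample_censored_latents(prob, conc, *err_ab, rng)
                y_complete = np.where(prob.cens, lat, prob.y)
            m = prob.omask
            f_obs = conc[m]
            e_obs = (y_complete - conc)[m]
            a_hat, b_hat = _update_error(spec.error_kind, err_ab[0], err_ab[1], f_obs, e_obs)
            if burn:
                a_new = min(max(a_hat, settings.annealing * err_ab[0]), growth * err_ab[0])
                b_new = min(max(b_hat, settings.annealing * err_ab[1]), growth * err_ab[1])
            else:
                a_new = err_ab[0] + gamma * (a_hat - err_ab[0])
                b_new = err_ab[1] + gamma * (b_hat - err_ab[1])
            err_ab = (min(a_new, a_max), min(b_new, b_max))

        trace_rows.append(_estimates_dict(spec, coefs, omega, err_ab) | {"iteration": it})

    trace = pd.DataFrame(trace_rows)
    estimates = _estimates_dict(spec, coefs, omega, err_ab)

    # convergence: relative drift of each free parameter across the smoothing phase
    warnings_: list[str] = []
    drift: dict[str, float] = {}
    smooth = trace.iloc[settings.n_burnin:]
    third = max(len(smooth) // 3, 1)
    for name in estimates:
        if name not in smooth:
            continue
        first = smooth[name].iloc[:third].median()
        last = smooth[name].iloc[-third:].median()
        scale = max(abs(estimates[name]), 0.1)
        drift[name] = abs(last - first) / scale
    converged = all(d < 0.25 for d in drift.values())
    if not converged:
        bad = {k: round(v, 3) for k, v in drift.items() if v >= 0.2}
        warnings_.append(f"parameter drift in smoothing phase exceeds tolerance: {bad}")
    for p_idx, p in enumerate(spec.params):
        if omega_free[p_idx] and omega[p_idx] < 0.01:
            warnings_.append(f"omega_{p.name} collapsed toward zero ({omega[p_idx]:.2e})")

    # conditional distributions at the final estimates (single stack of rows)
    ebe_samples, ebe_eta, ebe_map = _conditional_samples(
        base, coefs, omega, err_ab, settings, rng
    )
    shr = {}
    for p_idx, p in enumerate(spec.params):
        pooled = ebe_samples[:, :, p_idx].ravel()
        shr[p.name] = float(1.0 - np.std(pooled, ddof=1) / omega[p_idx]) if omega[p_idx] > 0 else np.nan

    fit = FitResult(
        spec=spec,
        settings=settings,
        estimates=estimates,
        se={},
        rse={},
        fim=None,
        fim_coords=(),
        loglik=None,
        loglik_se=None,
        bicc=None,
        ebe_eta=ebe_eta,
        ebe_map=ebe_map,
        ebe_samples=ebe_samples,
        shrinkage=shr,
        trace=trace,
        converged=converged,
        drift=drift,
        warnings=warnings_,
        n_subjects=base.n_sub,
        n_observations=base.n_obs_total,
        _problem=base,
        _coefs=coefs,
        _omega=omega,
        _err=err_ab,
    )

    if settings.compute_fim:
        _attach_fim(fit, rng)
    if settings.compute_loglik:
        ll, se = loglik_importance_sampling(fit, n_samples=settings.loglik_is_samples, rng=rng)
        fit.loglik, fit.loglik_se = ll, se
        fit.bicc = bicc(
            ll, base.n_sub, base.n_obs_total,
            spec.n_subject_level_params(), spec.n_obs_level_params(),
        )
    return fit


def _conditional_samples(prob, coefs, omega, err_ab, settings, rng):
    """MCMC samples from each subject's conditional eta distribution, plus
    conditional means and MAP modes."""
    P, R = prob.P, prob.n_rows
    mpred = prob.linear_predictor(coefs)
    eta = np.zeros((R, P))
    scales = np.tile(np.maximum(0.8 * omega, 1e-8), (R, 1))
    ll = prob.obs_loglik(_safe_exp(mpred + eta), *err_ab)
    inv2o2 = 1.0 / (2.0 * omega**2)
    keep = []
    n_iter = settings.ebe_burnin + settings.ebe_samples
    for it in range(n_iter):
        for p_ in range(P):
            prop = eta[:, p_] + scales[:, p_] * rng.standard_normal(R)
            eta_new = eta.copy()
            eta_new[:, p_] = prop
            ll_new = prob.obs_loglik(_safe_exp(mpred + eta_new), *err_ab)
            dlog = ll_new - ll - inv2o2[p_] * (prop**2 - eta[:, p_] ** 2)
            acc = np.log(rng.uniform(size=R)) < dlog
            eta[acc, p_] = prop[acc]
            ll = np.where(acc, ll_new, ll)
            if it < settings.ebe_burnin:
                scales[:, p_] *= np.exp(settings.adapt_rate * (acc - settings.target_accept))
        if it >= settings.ebe_burnin:
            keep.append(eta.copy())
    samples = np.stack(keep)  # (S, R, P)
    ebe_mean = samples.mean(axis=0)

    # MAP per subject by direct optimisation of the conditional log-density
    ebe_map = np.zeros((R, P))
    for r in range(R):
        row = _row_problem(prob, r)

        def neg(eta_r):
            th = _safe_exp(mpred[r] + eta_r)[None, :]
            return float(
                -(row.obs_loglik(th, *err_ab)[0] - np.sum(eta_r**2 * inv2o2))
            )

        res = optimize.minimize(neg, ebe_mean[r], method="Nelder-Mead",
                                options={"maxiter": 300, "xatol": 1e-5, "fatol": 1e-8})
        ebe_map[r] = res.x
    return samples, ebe_mean, ebe_map


def _row_problem(prob: _Problem, r: int) -> _Problem:
    import copy

    p = copy.copy(prob)
    for name in ("y", "cens", "omask", "DT", "dmask", "AMT"):
        setattr(p, name, getattr(prob, name)[r : r + 1])
    p.X = [x[r : r + 1] for x in prob.X]
    return p


def _fim_coords(spec: ModelSpec) -> list[str]:
    coords = []
    for p in spec.params:
        if not p.fixed:
            coords.append(f"{p.name}_pop")
        for t in p.covariates:
            if not t.fixed:
                coords.append(f"beta_{p.name}_log{t.covariate}")
    for p in spec.params:
        if not p.omega_fixed:
            coords.append(f"omega_{p.name}")
    if not spec.err_fixed:
        if spec.error_kind in ("constant", "combined1", "combined2"):
            coords.append("err_a")
        if spec.error_kind in ("proportional", "combined1", "combined2"):
            coords.append("err_b")
    return coords


def _attach_fim(fit: FitResult, rng: np.random.Generator) -> None:
    """Observed-information estimate from per-subject conditional-mean scores.

    By Fisher's identity the marginal score of a subject equals the
    conditional expectation of its complete-data score; the information is
    estimated as the outer-product (BHHH) sum over independent subjects,
    on the transformed scale (log for positive parameters, identity for
    betas).  Standard errors map back to the natural scale by the delta
    method, so RSE% of a log-parameter equals 100 x SE(log scale).
    """
    prob, spec = fit._problem, fit.spec
    coefs, omega, (a, b) = fit._coefs, fit._omega, fit._err
    samples = fit.ebe_samples  # (S, n_sub, P)
    S, n, P = samples.shape
    coords = _fim_coords(spec)
    if not coords:
        return
    mpred = prob.linear_predictor(coefs)
    score_sum = np.zeros((n, len(coords)))
    kind = spec.error_kind
    for s_ in range(S):
        eta = samples[s_]
        conc = prob.predict(np.exp(mpred + eta))
        sd = prob.residual_sd(conc, a, b)
        y = prob.y
        if prob.cens.any():
            lat = _sample_censored_latents(prob, conc, a, b, rng)
            y = np.where(prob.cens, lat, prob.y)
        e = np.where(prob.omask, y - conc, 0.0)
        t_stat = np.where(prob.omask, e * e / sd**3 - 1.0 / sd, 0.0)
        vals = []
        for p_idx, p in enumerate(spec.params):
            sc = eta[:, p_idx] / omega[p_idx] ** 2
            if not p.fixed:
                vals.append(sc * prob.X[p_idx][:, 0])
            for t_idx, t in enumerate(p.covariates):
                if not t.fixed:
                    vals.append(sc * prob.X[p_idx][:, 1 + t_idx])
        for p_idx, p in enumerate(spec.params):
            if not p.omega_fixed:
                vals.append(eta[:, p_idx] ** 2 / omega[p_idx] ** 2 - 1.0)
        if not spec.err_fixed:
            if kind == "constant":
                vals.append(a * t_stat.sum(axis=1))
            elif kind == "proportional":
                vals.append(b * (t_stat * conc).sum(axis=1))
            elif kind == "combined1":
                vals.append(a * t_stat.sum(axis=1))
                vals.append(b * (t_stat * conc).sum(axis=1))
            else:  # combined2: sd = sqrt(a^2 + b^2 f^2)
                vals.append(a * (t_stat * (a / sd)).sum(axis=1))
                vals.append(b * (t_stat * (b * conc * conc / sd)).sum(axis=1))
        score_sum += np.column_stack(vals)
    sbar = score_sum / S
    fim = sbar.T @ sbar
    fit.fim = fim
    fit.fim_coords = tuple(coords)
    try:
        cov = np.linalg.inv(fim)
        se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        fit.warnings.append("information matrix is singular; no standard errors")
        return
    for name, se_log in zip(coords, se_t):
        est = fit.estimates[name]
        if name.startswith("beta"):
            fit.se[name] = float(se_log)
            fit.rse[name] = float(100.0 * se_log / abs(est)) if est != 0 else np.inf
        else:
            fit.se[name] = float(est * se_log)  # delta method to natural scale
            fit.rse[name] = float(100.0 * se_log)


def loglik_importance_sampling(
    fit: FitResult,
    n_samples: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Marginal log-likelihood by importance sampling around the conditional
    distributions; returns (loglik, Monte Carlo standard error)."""
    if n_samples is None:
        n_samples = fit.settings.loglik_is_samples
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    prob = fit._problem
    coefs, omega, (a, b) = fit._coefs, fit._omega, fit._err
    n, P = prob.n_sub, prob.P
    mpred = prob.linear_predictor(coefs)
    m = fit.ebe_samples.mean(axis=0)  # (n, P)
    # over-dispersed proposal; floored at a fraction of the prior SD so the
    # weights stay bounded even when the conditional chain barely moved
    s = np.maximum(fit.ebe_samples.std(axis=0, ddof=1) * 1.3, 0.3 * omega[None, :]) + 1e-12
    chunk = max(1, min(n_samples, 200))
    log_w_all = []
    done = 0
    while done < n_samples:
        k = min(chunk, n_samples - done)
        z = rng.standard_normal((k, n, P))
        eta = m[None] + s[None] * z
        theta = np.exp(mpred[None] + eta).reshape(k * n, P)
        big = _tiled_problem(prob, k)
        ll_obs = big.obs_loglik(theta, a, b).reshape(k, n)
        lp = -0.5 * (eta / omega[None, None, :]) ** 2 - np.log(omega)[None, None, :] - 0.5 * _LOG_2PI
        lq = -0.5 * z**2 - np.log(s)[None] - 0.5 * _LOG_2PI
        log_w_all.append(ll_obs + lp.sum(axis=2) - lq.sum(axis=2))
        done += k
    logw = np.concatenate(log_w_all, axis=0)  # (n_samples, n)
    mx = logw.max(axis=0)
    if not np.all(np.isfinite(mx)):
        raise RuntimeError("degenerate importance-sampling proposal: zero weight mass for a subject")
    w = np.exp(logw - mx[None])
    mean_w = w.mean(axis=0)
    ll = float(np.sum(np.log(mean_w) + mx))
    rel_se = w.std(axis=0, ddof=1) / (mean_w * math.sqrt(n_samples))
    return ll, float(np.sqrt(np.sum(rel_se**2)))


def _tiled_problem(prob: _Problem, k: int) -> _Problem:
    import copy

    p = copy.copy(prob)
    for name in ("y", "cens", "omask", "DT", "dmask", "AMT"):
        a_ = getattr(prob, name)
        setattr(p, name, np.tile(a_, (k,) + (1,) * (a_.ndim - 1)))
    p.X = [np.tile(x, (k, 1)) for x in prob.X]
    return p


def bicc(
    loglik: float,
    n_subjects: int,
    n_obs: int,
    n_subject_level_params: int,
    n_obs_level_params: int,
) -> float:
    """Corrected BIC with a hybrid penalty: subject-level parameters (fixed
    effects carrying random effects, covariate betas, omegas) are penalised
    by log(n_subjects) and observation-level parameters (residual-error
    constants) by log(n_obs)."""
    if min(n_subjects, n_obs, n_subject_level_params, n_obs_level_params) < 0:
        raise ValueError("counts must be >= 0")
    pen_sub = math.log(n_subjects) * n_subject_level_params if n_subject_level_params else 0.0
    pen_obs = math.log(n_obs) * n_obs_level_params if n_obs_level_params else 0.0
    return -2.0 * loglik + pen_sub + pen_obs


def wald_test(
    beta_hat: float,
    se: float | None = None,
    rse_percent: float | None = None,
) -> float:
    """Two-sided Wald p-value for a covariate coefficient.

    The standard error may be given directly or as an RSE in percent of
    ``|beta_hat|`` (as printed in population-PK parameter tables).
    """
    if se is None:
        if rse_percent is None:
            raise ValueError("provide se or rse_percent")
        se = abs(beta_hat) * rse_percent / 100.0
    if se <= 0:
        raise ValueError("se must be > 0")
    z = beta_hat / se
    return float(2.0 * stats.norm.sf(abs(z)))


def ebe_conditional(
    fit: FitResult,
    subject: int | None = None,
    rng: np.random.Generator | int | None = None,
    n_samples: int | None = None,
) -> dict:
    """Conditional-mode eta and fresh conditional-distribution samples.

    ``subject`` is the subject index (None = all subjects).  Deterministic
    given the rng seed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    settings = fit.settings if n_samples is None else replace(fit.settings, ebe_samples=n_samples)
    samples, mean, mode = _conditional_samples(
        fit._problem, fit._coefs, fit._omega, fit._err, settings, rng
    )
    if subject is None:
        return {"mode": mode, "mean": mean, "samples": samples}
    return {"mode": mode[subject], "mean": mean[subject], "samples": samples[:, subject, :]}


def shrinkage(eta_samples: np.ndarray, omega: float) -> float:
    """Eta-shrinkage ``1 - sd(eta_i) / omega`` from conditional samples.

    ``eta_samples`` pools the conditional-distribution draws across
    subjects.  ``omega = 0`` is undefined and returns NaN.
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if omega == 0:
        return float("nan")
    arr = np.asarray(eta_samples, dtype=float).ravel()
    return float(1.0 - np.std(arr, ddof=1) / omega)


def naive_two_stage_init(dataset: PKDataset) -> dict[str, float]:
    """Rough curve-stripping initial values (V1 from the first post-dose
    sample, clearance from the terminal slope); useful to seed SAEM when no
    external initial values exist."""
    v1s, ks = [], []
    for s in dataset.subjects():
        if not len(s.doses) or not len(s.obs_times):
            continue
        dv = np.where(s.cens, np.nan, s.dv)
        ok = np.isfinite(dv) & (dv > 0)
        if ok.sum() < 3:
            continue
        t, c = s.obs_times[ok], dv[ok]
        first = np.argmin(t)
        v1s.append(s.doses[0].amount / c[first])
        tail = slice(max(len(t) - 4, 0), len(t))
        slope = np.polyfit(t[tail], np.log(c[tail]), 1)[0]
        if slope < 0:
            ks.append(-slope)
    v1 = float(np.median(v1s)) if v1s else 20.0
    k = float(np.median(ks)) if ks else 0.3
    cl = max(k * v1 * 2.0, 1e-3)
    return {"cl": cl, "v1": v1, "q": cl, "v2": v1}


def covariate_selection(
    dataset: PKDataset,
    base_spec: ModelSpec,
    candidates: list[tuple[str, str, float]],
    settings: SaemSettings | None = None,
    n_boot: int = 0,
    boot_rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One-at-a-time covariate screening with the four retention criteria.

    ``candidates`` are (parameter, covariate, reference) triples.  For each
    candidate the extended model is fitted and the log records: the BICc
    change, the BSV (omega) change on the target parameter, the Wald p-value
    of the coefficient, and — when ``n_boot > 0`` — a parametric-bootstrap
    percentile CI for the coefficient.  Retention requires a BICc drop, a
    BSV drop, Wald p < .05 and a bootstrap CI excluding zero.
    """
    if settings is None:
        settings = SaemSettings()
    base_fit = saem_fit(dataset, base_spec, settings)
    rows = []
    for par, cov, ref in candidates:
        params = []
        for p in base_spec.params:
            if p.name == par:
                params.append(replace(p, covariates=p.covariates + (CovariateTerm(cov, ref),)))
            else:
                params.append(p)
        ext_spec = replace(base_spec, params=tuple(params))
        ext_fit = saem_fit(dataset, ext_spec, settings)
        beta_name = f"beta_{par}_log{cov}"
        beta = ext_fit.estimates[beta_name]
        p_wald = (
            wald_test(beta, se=ext_fit.se[beta_name]) if beta_name in ext_fit.se else np.nan
        )
        ci = (np.nan, np.nan)
        if n_boot > 0:
            from .diagnostics import parametric_bootstrap_sse

            sse = parametric_bootstrap_sse(
                ext_fit, dataset, n_rep=n_boot, settings=settings, rng=boot_rng
            )
            row = sse.table[sse.table["parameter"] == beta_name]
            if len(row):
                ci = (float(row["ci_lo"].iloc[0]), float(row["ci_hi"].iloc[0]))
        d_bicc = (
            ext_fit.bicc - base_fit.bicc
            if ext_fit.bicc is not None and base_fit.bicc is not None
            else np.nan
        )
        d_bsv = ext_fit.estimates[f"omega_{par}"] - base_fit.estimates[f"omega_{par}"]
        keep = (
            (np.isnan(d_bicc) or d_bicc < 0)
            and d_bsv < 0
            and (np.isnan(p_wald) or p_wald < 0.05)
            and (np.isnan(ci[0]) or (ci[0] * ci[1] > 0))
        )
        rows.append(
            {
                "parameter": par,
                "covariate": cov,
                "beta": beta,
                "delta_bicc": d_bicc,
                "delta_bsv": d_bsv,
                "wald_p": p_wald,
                "boot_ci_lo": ci[0],
                "boot_ci_hi": ci[1],
                "retain": keep,
            }
        )
    return pd.DataFrame(rows)
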