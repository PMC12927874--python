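"""Internal model validation: pcVPC, NPDE, IWRES, parametric bootstrap.

All checks are simulation-based: replicate datasets are drawn under the
study design from the fitted model and compared with the observations.
Censored (below-LLOQ) observations are carried along and flagged but are
excluded from percentile and test statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular
from scipy.special import ndtri

from .dataset import PKDataset
from .compartmental import concentration
from .estimation import FitResult, ModelSpec, SaemSettings, saem_fit
from .popmodel import (
    Covariates,
    PopulationModel,
    residual_sd,
    sample_individual,
    typical_params,
)

__all__ = ["VPCResult", "SSEResult", "pc_vpc", "npde", "iwres", "parametric_bootstrap_sse"]

_PCTS = (10, 50, 90)


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary.

    ``bands`` has one row per (bin, percentile) with the observed percentile
    and the simulation-based prediction interval for that percentile;
    ``coverage`` is the fraction of (prediction-corrected, uncensored)
    observations inside the pooled 90% prediction band of their bin.
    """

    bands: pd.DataFrame
    coverage: float
    n_sim: int
    binning: str
    points: pd.DataFrame  # per-observation: axis value, pc value, censored flag

    @property
    def outlier_bins(self) -> pd.DataFrame:
        return self.bands[self.bands["outlier"]]


@dataclass
class SSEResult:
    """Stochastic simulation-estimation (parametric bootstrap) summary."""

    table: pd.DataFrame  # parameter, reference, median, ci_lo, ci_hi, bias_pct
    estimates: pd.DataFrame  # one row per converged replicate
    n_rep: int
    convergence_rate: float

    def bias_pct(self, parameter: str) -> float:
        row = self.table[self.table["parameter"] == parameter]
        if not len(row):
            raise KeyError(parameter)
        return float(row["bias_pct"].iloc[0])


def _as_model(model: PopulationModel | FitResult) -> PopulationModel:
    if isinstance(model, FitResult):
        return model.to_population_model()
    return model


def _time_after_dose(times: np.ndarray, dose_times: np.ndarray) -> np.ndarray:
    out = np.empty_like(times)
    for j, t in enumerate(times):
        prior = dose_times[dose_times <= t + 1e-12]
        out[j] = t - (prior.max() if len(prior) else 0.0)
    return out


def _quantile_bins(axis: np.ndarray, n_bins: int, min_per_bin: int = 3) -> np.ndarray:
    """Bin assignment by quantile edges; sparse bins merged with a neighbour."""
    qs = np.quantile(axis, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(qs)
    idx = np.clip(np.searchsorted(edges, axis, side="right") - 1, 0, len(edges) - 2)
    # merge bins holding fewer than min_per_bin points into the left neighbour
    changed = True
    while changed:
        changed = False
        for b in np.unique(idx):
            if (idx == b).sum() < min_per_bin and len(np.unique(idx)) > 1:
                target = b - 1 if b > idx.min() else b + 1
                idx[idx == b] = target
                changed = True
                break
    # re-label consecutively
    _, idx = np.unique(idx, return_inverse=True)
    return idx


def pc_vpc(
    dataset: PKDataset,
    model: PopulationModel | FitResult,
    n_sim: int = 1000,
    binning: str = "time",
    n_bins: int = 8,
    rng: np.random.Generator | int | None = None,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Observed and simulated values are corrected by the bin-median population
    prediction (``pcY = Y * median(PRED_bin) / PRED``), so dose and
    covariate differences between subjects do not inflate the percentile
    bands.  ``binning`` is "time" (absolute) or "tad" (time after the most
    recent dose, folding all interdose intervals together).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    if binning not in ("time", "tad"):
        raise ValueError("binning must be 'time' or 'tad'")
    model = _as_model(model)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    subs = list(dataset.subjects())
    obs_model = model.observation_model

    pred, axis, yobs, cens = [], [], [], []
    sims_per_sub = []
    for s in subs:
        tp = typical_params(model, s.covariates)
        p = concentration(tp, s.doses, s.obs_times)
        pred.append(p)
        dose_times = np.array([d.time for d in s.doses])
        axis.append(s.obs_times if binning == "time" else _time_after_dose(s.obs_times, dose_times))
        yobs.append(np.where(s.cens, s.lloq, s.dv))
        cens.append(s.cens)
        # simulate replicates for this subject's design
        c_ind = np.empty((n_sim, len(s.obs_times)))
        for r in range(n_sim):
            ind = sample_individual(model, s.covariates, rng)
            c_ind[r] = concentration(ind.structural, s.doses, s.obs_times)
        sd = residual_sd(obs_model, np.clip(c_ind, 0.0, None))
        sims_per_sub.append(c_ind + np.asarray(sd) * rng.standard_normal(c_ind.shape))

    pred = np.concatenate(pred)
    axis = np.concatenate(axis)
    yobs = np.concatenate(yobs)
    cens = np.concatenate(cens).astype(bool)
    sims = np.concatenate(sims_per_sub, axis=1)  # (n_sim, n_obs)

    bins = _quantile_bins(axis, n_bins)
    pc_obs = np.empty_like(yobs)
    pc_sims = np.empty_like(sims)
    for b in np.unique(bins):
        m = bins == b
        med_pred = np.median(pred[m])
        corr = med_pred / np.maximum(pred[m], 1e-12)
        pc_obs[m] = yobs[m] * corr
        pc_sims[:, m] = sims[:, m] * corr[None, :]

    rows = []
    inside = 0
    n_unc = 0
    for b in np.unique(bins):
        m = bins == b
        mu = m & ~cens
        band_lo = np.quantile(pc_sims[:, m], 0.05)
        band_hi = np.quantile(pc_sims[:, m], 0.95)
        if mu.any():
            inside += int(np.sum((pc_obs[mu] >= band_lo) & (pc_obs[mu] <= band_hi)))
            n_unc += int(mu.sum())
        for pct in _PCTS:
            obs_p = np.quantile(pc_obs[mu], pct / 100) if mu.any() else np.nan
            sim_p = np.quantile(pc_sims[:, m], pct / 100, axis=1)  # per replicate
            lo, hi = np.quantile(sim_p, [0.05, 0.95])
            rows.append(
                {
                    "bin": int(b),
                    "axis_lo": float(axis[m].min()),
                    "axis_hi": float(axis[m].max()),
                    "percentile": pct,
                    "observed": obs_p,
                    "pi_lo": lo,
                    "pi_hi": hi,
                    "outlier": bool(np.isfinite(obs_p) and not (lo <= obs_p <= hi)),
                }
            )
    bands = pd.DataFrame(rows)
    # percentile ordering within bins is guaranteed by construction of quantiles
    points = pd.DataFrame({"axis": axis, "pc_value": pc_obs, "censored": cens, "bin": bins})
    coverage = inside / n_unc if n_unc else float("nan")
    return VPCResult(bands=bands, coverage=coverage, n_sim=n_sim, binning=binning, points=points)


def npde(
    dataset: PKDataset,
    model: PopulationModel | FitResult,
    n_sim: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Normalized prediction distribution errors with normality diagnostics.

    Each subject's observation vector is decorrelated with the simulation
    mean and covariance (lower-triangular factor), ranks are mapped through
    the inverse normal CDF.  Returns per-observation NPDE (NaN at censored
    rows, which are excluded from the tests), a Shapiro-Wilk p-value, a
    sign-test (symmetry about zero) p-value, and the pooled values.
    """
    model = _as_model(model)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    obs_model = model.observation_model
    if model.err_a == 0 and model.err_b == 0:
        raise ValueError("NPDE is undefined for a deterministic (zero residual error) model")
    all_npde, all_axis, all_cens = [], [], []
    for s in dataset.subjects():
        n_i = len(s.obs_times)
        sims = np.empty((n_sim, n_i))
        for r in range(n_sim):
            ind = sample_individual(model, s.covariates, rng)
            c = concentration(ind.structural, s.doses, s.obs_times)
            sims[r] = c + np.asarray(residual_sd(obs_model, c)) * rng.standard_normal(n_i)
        mu = sims.mean(axis=0)
        cov = np.cov(sims.T) if n_i > 1 else np.array([[sims.var(ddof=1)]])
        cov = np.atleast_2d(cov) + 1e-12 * np.eye(n_i)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("simulation covariance is singular; cannot decorrelate") from exc
        y = np.where(s.cens, s.lloq, s.dv)
        y_dec = solve_triangular(L, y - mu, lower=True)
        sims_dec = solve_triangular(L, (sims - mu).T, lower=True).T
        pde = ((sims_dec < y_dec[None, :]).sum(axis=0) + 0.5) / (n_sim + 1.0)
        all_npde.append(ndtri(pde))
        all_axis.append(s.obs_times)
        all_cens.append(s.cens)
    vals = np.concatenate(all_npde)
    cens = np.concatenate(all_cens).astype(bool)
    times = np.concatenate(all_axis)
    kept = vals[~cens]
    shapiro_p = float(stats.shapiro(kept).pvalue)
    n_pos = int((kept > 0).sum())
    sign_p = float(stats.binomtest(n_pos, len(kept), 0.5).pvalue)
    out = pd.DataFrame({"time": times, "npde": np.where(cens, np.nan, vals), "censored": cens})
    return {
        "table": out,
        "values": kept,
        "shapiro_p": shapiro_p,
        "symmetry_p": sign_p,
        "mean": float(kept.mean()),
        "sd": float(kept.std(ddof=1)),
    }


def iwres(fit: FitResult) -> pd.DataFrame:
    """Individual weighted residuals at the empirical Bayes estimates.

    ``(y - f_individual) / sd(f_individual)`` for uncensored rows; censored
    rows are kept in the table with NaN and the flag set.
    """
    prob = fit._problem
    mpred = prob.linear_predictor(fit._coefs)
    theta = np.exp(mpred + fit.ebe_eta)
    conc = prob.predict(theta)
    a, b = fit._err
    sd = prob.residual_sd(conc, a, b)
    res = (prob.y - conc) / sd
    rows = []
    for i, sid in enumerate(prob.subject_ids):
        m = prob.omask[i]
        for j in np.where(m)[0]:
            c = bool(prob.cens[i, j])
            rows.append(
                {
                    "id": sid,
                    "ipred": conc[i, j],
                    "iwres": np.nan if c else res[i, j],
                    "censored": c,
                }
            )
    return pd.DataFrame(rows)


def parametric_bootstrap_sse(
    model: PopulationModel | FitResult,
    design: PKDataset,
    n_rep: int = 1000,
    settings: SaemSettings | None = None,
    rng: np.random.Generator | int | None = None,
    spec: ModelSpec | None = None,
) -> SSEResult:
    """Parametric bootstrap by stochastic simulation and estimation (SSE).

    Each replicate simulates a dataset from the generating model under the
    fixed study design (same subjects, covariates, dose events and sampling
    times, with [0, LLOQ] censoring applied) and refits it by SAEM.  The
    summary reports, per free parameter, the replicate median, the
    2.5-97.5 percentile CI, and the bias
    ``(mean(estimates) - reference) / reference * 100`` against the
    generating value.  Non-converged replicates are counted in
    ``convergence_rate`` and excluded from the summary statistics (their
    estimates remain available in ``estimates``); they are never imputed.
    """
    gen = _as_model(model)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if settings is None:
        settings = SaemSettings(compute_loglik=False, compute_fim=False)
    if spec is None:
        spec = ModelSpec.from_population_model(gen)
    subs = list(design.subjects())
    obs_model = gen.observation_model
    est_rows = []
    n_conv = 0
    for rep in range(n_rep):
        frames = []
        for s in subs:
            ind = sample_individual(gen, s.covariates, rng)
            c = concentration(ind.structural, s.doses, s.obs_times)
            sd = np.asarray(residual_sd(obs_model, c))
            y = c + sd * rng.standard_normal(c.shape)
            cen = y < gen.lloq
            base = {"id": s.subject_id, "age": s.covariates.age, "tbw": s.covariates.tbw,
                    "albumin": s.covariates.albumin, "creatinine": s.covariates.creatinine}
            rows = [
                {**base, "time": d.time, "evid": "dose", "amt": d.amount,
                 "dv": np.nan, "cens": 0, "lloq": np.nan}
                for d in s.doses
            ]
            rows += [
                {**base, "time": t, "evid": "obs", "amt": np.nan,
                 "dv": (np.nan if cen[j] else y[j]), "cens": int(cen[j]), "lloq": gen.lloq}
                for j, t in enumerate(s.obs_times)
            ]
            frames.append(pd.DataFrame(rows))
        sim_ds = PKDataset(pd.concat(frames, ignore_index=True))
        fit = saem_fit(sim_ds, spec, replace(settings, seed=settings.seed + rep))
        if fit.converged:
            n_conv += 1
        est_rows.append({**fit.estimates, "replicate": rep, "converged": fit.converged})
    est = pd.DataFrame(est_rows)
    ref_map = {
            "cl_pop": gen.cl_pop, "v1_pop": gen.v1_pop, "q_pop": gen.q_pop, "v2_pop": gen.v2_pop,
            "beta_cl_logage": gen.beta_cl_logage, "beta_v2_logage": gen.beta_v2_logage,
            "omega_cl": gen.omega_cl, "omega_v1": gen.omega_v1,
            "omega_q": gen.omega_q, "omega_v2": gen.omega_v2,
            "err_a": gen.err_a, "err_b": gen.err_b,
        }
    free = _free_names(spec)
    conv_est = est[est["converged"]] if est["converged"].any() else est
    rows = []
    for name in free:
        vals = conv_est[name].to_numpy(dtype=float)
        ref = ref_map.get(name, np.nan)
        rows.append(
            {
                "parameter": name,
                "reference": ref,
                "median": float(np.median(vals)),
                "ci_lo": float(np.quantile(vals, 0.025)),
                "ci_hi": float(np.quantile(vals, 0.975)),
                "bias_pct": float((vals.mean() - ref) / ref * 100.0) if np.isfinite(ref) and ref != 0 else np.nan,
            }
        )
    return SSEResult(
        table=pd.DataFrame(rows),
        estimates=est,
        n_rep=n_rep,
        convergence_rate=n_conv / n_rep,
    )


def _free_names(spec: ModelSpec) -> list[str]:
    names = []
    for p in spec.params:
        if not p.fixed:
            names.append(f"{p.name}_pop")
        for t in p.covariates:
            if not t.fixed:
                names.append(f"beta_{p.name}_log{t.covariate}")
    for p in spec.params:
        if not p.omega_fixed:
            names.append(f"omega_{p.name}")
    if not spec.err_fixed:
        if spec.error_kind in ("constant", "combined1", "combined2"):
            names.append("err_a")
        if spec.error_kind in ("proportional", "combined1", "combined2"):
            names.append("err_b")
    return names
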