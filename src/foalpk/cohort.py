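"""Synthetic study-like cohorts: covariates, sampling schedules, datasets.

The real study enrolled 12 hospitalized neonatal foals (9-194.5 h old,
median body weight 48.5 kg) treated with 20 mg/kg IV ampicillin every 6 h
and sampled a median of 13 times over the first 48 h; 17/205 samples fell
below the 0.3 mg/L quantification limit.  Only summary statistics of that
design are public, so this module draws covariates from distributions
anchored to the printed medians and interquartile ranges and builds
sampling schedules with the same dense-early + peak/trough shape.  Every
generated object is a synthetic stand-in for the study design, not a
reconstruction of the raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartmental import Regimen
from .dataset import PKDataset
from .popmodel import Covariates, PopulationModel, sample_individual, simulate_observations

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "sampling_schedule",
    "generate_dataset",
    "mic_fixture",
    "quantile_sampler",
]

#: Printed covariate summary of the 12-foal cohort: median [IQR].
COHORT_SUMMARY = {
    "age": (78.0, 19.7, 180.0),  # h
    "tbw": (48.5, 38.0, 60.0),  # kg
    "albumin": (28.9, 26.5, 30.7),  # g/L
    "creatinine": (12.8, 9.5, 14.7),  # mg/L
}

#: Quantile anchors used to sample ages (h): observed min, Q1, median, Q3, max.
AGE_QUANTILES = ((0.0, 9.0), (0.25, 19.7), (0.5, 78.0), (0.75, 180.0), (1.0, 194.5))

#: Quantile anchors for the per-foal sample count (median 13, range 12-24).
SAMPLE_COUNT_QUANTILES = ((0.0, 12.0), (0.25, 12.0), (0.5, 13.0), (0.75, 24.0), (1.0, 24.0))


def quantile_sampler(anchors, rng: np.random.Generator, size: int, log_scale: bool = True) -> np.ndarray:
    """Sample from a distribution given by (probability, value) quantile anchors.

    The inverse CDF is interpolated piecewise-linearly (on the log scale by
    default, keeping values positive), so the anchored quantiles — in
    particular the median and IQR — are reproduced by construction.
    """
    p = np.array([a[0] for a in anchors], dtype=float)
    v = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(p) <= 0) or np.any(np.diff(v) < 0):
        raise ValueError("anchors must have strictly increasing probabilities and non-decreasing values")
    u = rng.uniform(0.0, 1.0, size=size)
    if log_scale:
        return np.exp(np.interp(u, p, np.log(v)))
    return np.interp(u, p, v)


def _lognormal_from_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matching the printed median and IQR."""
    sigma = 0.5 * (np.log(q3 / median) + np.log(median / q1)) / 0.67448975
    return np.log(median), sigma


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic foal cohort.

    Defaults emulate the study: 12 foals, ages spanning 9-194.5 h with the
    printed quartiles, log-normal body weight (median 48.5 kg, IQR 38-60),
    normal albumin, log-normal creatinine, a median of 13 samples per foal
    over a 48-h horizon and a 0.3 mg/L LLOQ.  ``creatinine_outlier`` makes
    the youngest foal carry the extreme 63.8 mg/L serum creatinine seen in
    the study, for covariate-robustness experiments.
    """

    n_foals: int = 12
    age_quantiles: tuple = AGE_QUANTILES
    tbw_median: float = 48.5
    tbw_iqr: tuple[float, float] = (38.0, 60.0)
    albumin_median: float = 28.9
    albumin_iqr: tuple[float, float] = (26.5, 30.7)
    creatinine_median: float = 12.8
    creatinine_iqr: tuple[float, float] = (9.5, 14.7)
    sample_count_quantiles: tuple = SAMPLE_COUNT_QUANTILES
    horizon: float = 48.0
    lloq: float = 0.3
    creatinine_outlier: bool = False

    def __post_init__(self) -> None:
        if self.n_foals < 1:
            raise ValueError("n_foals must be >= 1")
        if self.horizon <= 0 or self.lloq <= 0:
            raise ValueError("horizon and lloq must be > 0")


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a covariate table (id, age, tbw, albumin, creatinine)."""
    n = spec.n_foals
    age = quantile_sampler(spec.age_quantiles, rng, n)
    mu, sig = _lognormal_from_iqr(spec.tbw_median, *spec.tbw_iqr)
    tbw = np.exp(rng.normal(mu, sig, size=n))
    alb_sigma = (spec.albumin_iqr[1] - spec.albumin_iqr[0]) / 1.3489795
    albumin = np.abs(rng.normal(spec.albumin_median, alb_sigma, size=n))
    mu, sig = _lognormal_from_iqr(spec.creatinine_median, *spec.creatinine_iqr)
    creat = np.exp(rng.normal(mu, sig, size=n))
    if spec.creatinine_outlier:
        creat[int(np.argmin(age))] = 63.8
    return pd.DataFrame(
        {
            "id": [f"F{i+1:02d}" for i in range(n)],
            "age": age,
            "tbw": tbw,
            "albumin": albumin,
            "creatinine": creat,
        }
    )


def sampling_schedule(
    spec: CohortSpec, rng: np.random.Generator, interval: float = 6.0
) -> np.ndarray:
    """Observation times (h) for one foal: dense early, then peak/trough pairs.

    The first dosing interval is sampled densely (0.25-4 h), later intervals
    contribute a post-dose peak and a pre-dose trough; the total count is
    drawn from the study's per-foal distribution (median 13, range 12-24)
    and all times stay strictly inside the 48-h horizon.
    """
    n_samples = int(np.round(quantile_sampler(spec.sample_count_quantiles, rng, 1)[0]))
    early = [0.25, 0.5, 1.0, 2.0, 4.0]
    later: list[float] = []
    dose_times = np.arange(interval, spec.horizon, interval)
    for td in dose_times:
        later.append(td + 0.25)  # peak shortly after the bolus
        later.append(min(td + interval, spec.horizon) - 0.1)  # trough just before the next
    later = sorted(t for t in later if t < spec.horizon)
    extra = max(n_samples - len(early), 0)
    if extra >= len(later):
        chosen = later
    else:
        idx = rng.choice(len(later), size=extra, replace=False)
        chosen = [later[i] for i in sorted(idx)]
    times = np.array(sorted(set(early[: min(n_samples, len(early))] + chosen)))
    return times


def generate_dataset(
    spec: CohortSpec,
    model: PopulationModel,
    regimen: Regimen | None = None,
    rng: np.random.Generator | None = None,
    cohort: pd.DataFrame | None = None,
    schedules: list[np.ndarray] | None = None,
) -> PKDataset:
    """Simulate a complete study-like dataset from a population model.

    Dose rows follow the regimen (default 20 mg/kg q6h over 48 h) resolved
    to absolute mg at each foal's weight; observation rows carry residual
    error and [0, LLOQ] censoring.  Passing a fixed ``cohort`` and
    ``schedules`` keeps the design constant across replicates (as in
    simulation-estimation studies); otherwise both are drawn from ``spec``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if regimen is None:
        regimen = Regimen(dose_per_kg=20.0, interval=6.0, horizon=spec.horizon)
    if cohort is None:
        cohort = generate_cohort(spec, rng)
    if schedules is None:
        schedules = [sampling_schedule(spec, rng, regimen.interval) for _ in range(len(cohort))]
    model = model.with_updates(lloq=spec.lloq)
    rows = []
    for (idx, foal), times in zip(cohort.iterrows(), schedules):
        cov = Covariates(
            age=float(foal["age"]),
            tbw=float(foal["tbw"]),
            albumin=float(foal.get("albumin", np.nan)),
            creatinine=float(foal.get("creatinine", np.nan)),
        )
        indiv = sample_individual(model, cov, rng)
        doses = regimen.dose_events(cov.tbw)
        obs = simulate_observations(model, indiv, doses, times, rng)
        base = {
            "id": foal["id"],
            "age": cov.age,
            "tbw": cov.tbw,
            "albumin": foal.get("albumin", np.nan),
            "creatinine": foal.get("creatinine", np.nan),
        }
        for d in doses:
            rows.append({**base, "time": d.time, "evid": "dose", "amt": d.amount,
                         "dv": np.nan, "cens": 0, "lloq": np.nan})
        for r in obs.itertuples():
            rows.append({**base, "time": r.time, "evid": "obs", "amt": np.nan,
                         "dv": r.dv, "cens": int(r.cens), "lloq": spec.lloq})
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(["id", "time", "evid"], kind="stable").reset_index(drop=True)
    cols = ["id", "time", "evid", "amt", "dv", "cens", "lloq", "age", "tbw", "albumin", "creatinine"]
    return PKDataset(frame[cols])


def mic_fixture() -> pd.DataFrame:
    """MIC values of the 7 bacterial isolates from the study's culture-positive foals."""
    rows = [
        ("Streptococcus equi subsp. zooepidemicus", "blood", 0.06),
        ("Streptococcus equi subsp. zooepidemicus", "umbilical remnant", 0.06),
        ("Streptococcus equi subsp. zooepidemicus", "umbilical remnant", 0.06),
        ("Streptococcus equi subsp. zooepidemicus", "umbilical remnant", 0.06),
        ("Clostridium perfringens", "peritoneal fluid", 0.06),
        ("Bacillus licheniformis", "blood", 0.25),
        ("Enterococcus faecalis", "umbilical remnant", 0.5),
    ]
    return pd.DataFrame(rows, columns=["organism", "source", "mic"])
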