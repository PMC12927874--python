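"""NONMEM-style longitudinal dataset container and CSV round-trip.

One row per event.  Dose rows (``evid = "dose"``) carry the absolute amount
in mg; observation rows (``evid = "obs"``) carry the measured concentration
``dv`` in mg/L or, when below the quantification limit, ``cens = 1`` with an
empty ``dv`` and the LLOQ recorded in its own column.  Covariates (age h,
tbw kg, albumin g/L, creatinine mg/L) repeat on every row of a subject;
unknown extra columns are preserved as additional covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .compartmental import DoseEvent
from .popmodel import Covariates

__all__ = ["PKDataset", "SubjectData", "read_dataset", "write_dataset"]

MANDATORY_COLUMNS = ["id", "time", "evid", "amt", "dv", "cens", "lloq"]
KNOWN_COVARIATES = ["age", "tbw", "albumin", "creatinine"]
_FLOAT_FMT = "%.9g"


@dataclass(frozen=True)
class SubjectData:
    """One subject's events unpacked into arrays, ready for model evaluation."""

    subject_id: object
    doses: list[DoseEvent]
    obs_times: np.ndarray
    dv: np.ndarray  # NaN on censored rows
    cens: np.ndarray  # bool
    lloq: float
    covariates: Covariates


@dataclass
class PKDataset:
    """Validated cohort dataset wrapping a tidy pandas frame."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        self.frame = _validate(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["id"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.frame["evid"] == "obs").sum())

    @property
    def n_censored(self) -> int:
        obs = self.frame[self.frame["evid"] == "obs"]
        return int(obs["cens"].sum())

    def subjects(self) -> Iterator[SubjectData]:
        for sid, g in self.frame.groupby("id", sort=False):
            doses = [
                DoseEvent(float(r.time), float(r.amt))
                for r in g[g["evid"] == "dose"].itertuples()
            ]
            obs = g[g["evid"] == "obs"]
            cov = Covariates(
                age=float(g["age"].iloc[0]),
                tbw=float(g["tbw"].iloc[0]),
                albumin=float(g["albumin"].iloc[0]) if "albumin" in g and np.isfinite(g["albumin"].iloc[0]) else None,
                creatinine=float(g["creatinine"].iloc[0]) if "creatinine" in g and np.isfinite(g["creatinine"].iloc[0]) else None,
            )
            lloq_col = obs["lloq"].dropna()
            yield SubjectData(
                subject_id=sid,
                doses=doses,
                obs_times=obs["time"].to_numpy(dtype=float),
                dv=obs["dv"].to_numpy(dtype=float),
                cens=obs["cens"].to_numpy(dtype=bool),
                lloq=float(lloq_col.iloc[0]) if len(lloq_col) else np.nan,
                covariates=cov,
            )

    def drop_censored(self) -> "PKDataset":
        """Copy with censored observation rows deleted (naive BLQ handling)."""
        f = self.frame
        keep = ~((f["evid"] == "obs") & (f["cens"] == 1))
        return PKDataset(f[keep].reset_index(drop=True))


def _validate(frame: pd.DataFrame) -> pd.DataFrame:
    f = frame.copy()
    missing = [c for c in MANDATORY_COLUMNS if c not in f.columns]
    if missing:
        raise ValueError(f"dataset is missing mandatory columns: {missing}")
    if "age" not in f.columns or "tbw" not in f.columns:
        raise ValueError("dataset must carry 'age' and 'tbw' covariate columns")
    f["time"] = f["time"].astype(float)
    f["cens"] = f["cens"].fillna(0).astype(int)
    if np.any(f["time"] < 0):
        bad = f.index[f["time"] < 0].tolist()
        raise ValueError(f"negative event times at rows {bad}")
    if not set(f["evid"]).issubset({"dose", "obs"}):
        raise ValueError("evid must be 'dose' or 'obs'")
    for sid, g in f.groupby("id"):
        if (g["evid"] == "dose").sum() < 1:
            raise ValueError(f"subject {sid!r} has no dose rows")
        obs = g[g["evid"] == "obs"]
        if np.any(np.diff(obs["time"].to_numpy()) < 0):
            raise ValueError(f"subject {sid!r}: observation times are not monotone")
        cen = obs[obs["cens"] == 1]
        if len(cen) and cen["lloq"].isna().any():
            rows = cen.index[cen["lloq"].isna()].tolist()
            raise ValueError(f"subject {sid!r}: censored rows without an lloq value at rows {rows}")
        unc = obs[obs["cens"] == 0]
        if unc["dv"].isna().any():
            rows = unc.index[unc["dv"].isna()].tolist()
            raise ValueError(f"subject {sid!r}: uncensored observation rows with empty dv at rows {rows}")
        if np.any(unc["dv"].to_numpy(dtype=float) < 0):
            rows = unc.index[unc["dv"] < 0].tolist()
            raise ValueError(f"subject {sid!r}: negative dv at rows {rows}")
    return f.reset_index(drop=True)


def read_dataset(path: str | Path, autoflag_blq: bool = False) -> PKDataset:
    """Read a CSV dataset; optionally auto-censor uncensored dv below the LLOQ.

    With ``autoflag_blq`` off (the default), a quantified value below the
    recorded LLOQ raises a warning but is kept as-is.
    """
    f = pd.read_csv(path)
    ds = PKDataset(f)
    obs = ds.frame[(ds.frame["evid"] == "obs") & (ds.frame["cens"] == 0)]
    below = obs[obs["dv"] < obs["lloq"].fillna(0.0)]
    if len(below):
        import warnings

        if autoflag_blq:
            idx = below.index
            ds.frame.loc[idx, "cens"] = 1
            ds.frame.loc[idx, "dv"] = np.nan
        else:
            warnings.warn(
                f"{len(below)} observation rows have dv below the recorded LLOQ but cens=0 "
                f"(rows {below.index.tolist()}); pass autoflag_blq=True to censor them",
                stacklevel=2,
            )
    return ds


def write_dataset(dataset: PKDataset, path: str | Path) -> None:
    """Write the dataset as CSV (floats at 9 significant digits; read/write round-trips)."""
    dataset.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
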