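"""Closed-form concentration-time solutions for mammillary compartment models.

IV bolus input, first-order elimination, linear disposition.  The central
objects are :class:`StructuralParams` (one subject's clearance/volume
constants) and :func:`concentration`, the multi-dose superposition of the
bi-exponential unit response.  Time is in hours throughout and the first
dose defines ``t = 0``; doses are in mg of drug base, volumes in L, so
concentrations come out in mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "StructuralParams",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "DispositionConstants",
    "to_disposition_constants",
    "unit_impulse_response",
    "concentration",
    "free_concentration",
    "mammillary_concentration",
]

#: Unbound (free) fraction of ampicillin in foal plasma; average protein
#: binding of 15% reported for horses.
DEFAULT_FU = 0.85

# Relative root gap below which the repeated-root (critically damped)
# analytic form is used instead of the two-exponential form.
_REPEATED_ROOT_TOL = 1e-10


@dataclass(frozen=True)
class StructuralParams:
    """Structural constants of a 1- or 2-compartment disposition model.

    Parameters
    ----------
    cl : float
        Elimination clearance from the central compartment (L/h).
    v1 : float
        Central volume of distribution (L).
    q : float
        Intercompartmental clearance (L/h).  ``q = 0`` degenerates to the
        1-compartment model and ``v2`` is then ignored.
    v2 : float
        Peripheral volume of distribution (L).
    """

    cl: float
    v1: float
    q: float = 0.0
    v2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cl", "v1"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.q < 0 or not np.isfinite(self.q):
            raise ValueError(f"q must be non-negative, got {self.q!r}")
        if self.q > 0 and (not np.isfinite(self.v2) or self.v2 <= 0):
            raise ValueError(f"v2 must be strictly positive when q > 0, got {self.v2!r}")


@dataclass(frozen=True)
class DoseEvent:
    """A single IV bolus: ``amount`` mg given at ``time`` hours after the first dose."""

    time: float
    amount: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time!r}")
        if self.amount <= 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount!r}")


@dataclass(frozen=True)
class Regimen:
    """A repeated weight-based IV bolus regimen (e.g. 20 mg/kg q6h for 48 h)."""

    dose_per_kg: float
    interval: float
    horizon: float = 48.0

    def __post_init__(self) -> None:
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be > 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.horizon <= 0:
            raise ValueError("horizon must be > 0")

    @property
    def daily_dose(self) -> float:
        """Total daily dose in mg/kg/day."""
        return self.dose_per_kg * 24.0 / self.interval

    def dose_times(self) -> np.ndarray:
        """Bolus times within [0, horizon), starting at t = 0."""
        return np.arange(0.0, self.horizon, self.interval)

    def dose_events(self, tbw: float) -> list[DoseEvent]:
        """Resolve to absolute-mg dose events for a subject of ``tbw`` kg."""
        if tbw <= 0:
            raise ValueError("tbw must be > 0")
        amt = self.dose_per_kg * tbw
        return [DoseEvent(float(t), amt) for t in self.dose_times()]

    def label(self) -> str:
        return f"{self.dose_per_kg:g} mg/kg q{self.interval:g}h"


@dataclass(frozen=True)
class ConcentrationProfile:
    """Total and free concentration series on an ascending time grid."""

    times: np.ndarray
    total_conc: np.ndarray
    free_conc: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.times, "total": self.total_conc, "free": self.free_conc}
        )


class DispositionConstants(NamedTuple):
    """Micro-constants and bi-exponential coefficients of the unit response.

    For a unit (1 mg) bolus, ``C(t) = coef_a * exp(-alpha t) + coef_b * exp(-beta t)``
    with ``alpha >= beta > 0`` (``beta = 0`` in the 1-compartment limit means the
    second term is absent).
    """

    k10: float
    k12: float
    k21: float
    alpha: float
    beta: float
    coef_a: float
    coef_b: float


def to_disposition_constants(params: StructuralParams) -> DispositionConstants:
    """Macro/micro constants of the (degenerate or full) 2-compartment model.

    ``alpha`` and ``beta`` are the roots of
    ``s^2 - (k10 + k12 + k21) s + k10 k21 = 0`` with ``alpha > beta``; the
    unit-bolus coefficients are ``coef_a = (alpha - k21) / (v1 (alpha - beta))``
    and ``coef_b = (k21 - beta) / (v1 (alpha - beta))``.
    """
    k10 = params.cl / params.v1
    if params.q == 0.0:
        # 1-compartment: mono-exponential with rate k10.
        return DispositionConstants(k10, 0.0, 0.0, k10, 0.0, 1.0 / params.v1, 0.0)
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p
    root = np.sqrt(max(disc, 0.0))
    alpha = 0.5 * (s + root)
    # beta via the product to avoid cancellation when the roots are far apart
    beta = p / alpha
    if alpha - beta <= _REPEATED_ROOT_TOL * alpha:
        # repeated root: coefficients are not defined; callers switch forms
        lam = 0.5 * s
        return DispositionConstants(k10, k12, k21, lam, lam, np.nan, np.nan)
    coef_a = (alpha - k21) / (params.v1 * (alpha - beta))
    coef_b = (k21 - beta) / (params.v1 * (alpha - beta))
    return DispositionConstants(k10, k12, k21, alpha, beta, coef_a, coef_b)


def unit_impulse_response(params: StructuralParams) -> Callable[[np.ndarray], np.ndarray]:
    """Central-compartment concentration per mg of bolus, as a vectorised callable.

    Handles the 1-compartment, distinct-root 2-compartment and (critically
    damped) repeated-root cases; returns 0 for negative times.
    """
    d = to_disposition_constants(params)
    if d.beta == 0.0:  # 1-compartment
        inv_v1, k = 1.0 / params.v1, d.k10

        def f1(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            return np.where(t >= 0.0, inv_v1 * np.exp(-k * np.clip(t, 0.0, None)), 0.0)

        return f1
    if np.isnan(d.coef_a):  # repeated root lam: C(t) = e^{-lam t} (1 + (k21-lam) t) / v1
        lam, k21, inv_v1 = d.alpha, d.k21, 1.0 / params.v1

        def frep(t: np.ndarray) -> np.ndarray:
            t = np.asarray(t, dtype=float)
            tc = np.clip(t, 0.0, None)
            return np.where(t >= 0.0, inv_v1 * np.exp(-lam * tc) * (1.0 + (k21 - lam) * tc), 0.0)

        return frep

    ca, cb, al, be = d.coef_a, d.coef_b, d.alpha, d.beta

    def f2(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tc = np.clip(t, 0.0, None)
        return np.where(t >= 0.0, ca * np.exp(-al * tc) + cb * np.exp(-be * tc), 0.0)

    return f2


def concentration(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    t_grid: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Total plasma concentration (mg/L) by linear superposition over dose events.

    The profile is right-continuous at dose times (the bolus is included at
    its own time, so ``C(0) = D / v1`` for a dose at ``t = 0``) and zero
    before the first dose.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1:
        raise ValueError("t_grid must be one-dimensional")
    if np.any(t < 0):
        raise ValueError("t_grid entries must be >= 0 (first dose defines t = 0)")
    if np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be ascending")
    f = unit_impulse_response(params)
    out = np.zeros_like(t)
    for d in doses:
        out += d.amount * f(t - d.time)
    return out


def free_concentration(total: np.ndarray, fu: float = DEFAULT_FU) -> np.ndarray:
    """Unbound concentration: element-wise ``fu * total`` with ``0 < fu <= 1``."""
    if not (0.0 < fu <= 1.0):
        raise ValueError(f"unbound fraction fu must be in (0, 1], got {fu!r}")
    return fu * np.asarray(total, dtype=float)


def profile(
    params: StructuralParams,
    doses: Sequence[DoseEvent],
    t_grid: Sequence[float] | np.ndarray,
    fu: float = DEFAULT_FU,
) -> ConcentrationProfile:
    """Convenience wrapper bundling total and free concentrations."""
    t = np.asarray(t_grid, dtype=float)
    total = concentration(params, doses, t)
    return ConcentrationProfile(t, total, free_concentration(total, fu))


def _rate_matrix(cl: float, v1: float, peripherals: Sequence[tuple[float, float]]) -> np.ndarray:
    n = 1 + len(peripherals)
    k = np.zeros((n, n))
    k[0, 0] = -cl / v1
    for i, (q, v) in enumerate(peripherals, start=1):
        k[0, 0] -= q / v1
        k[0, i] = q / v
        k[i, 0] = q / v1
        k[i, i] = -q / v
    return k


def mammillary_concentration(
    cl: float,
    v1: float,
    peripherals: Sequence[tuple[float, float]],
    doses: Sequence[DoseEvent],
    t_grid: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Central concentration for an n-compartment mammillary model (IV bolus).

    Solved through the eigendecomposition of the first-order rate matrix, so
    any number of peripheral ``(q, v)`` compartments is supported.  Used for
    the 3-compartment candidate during structural model comparison; the 1-
    and 2-compartment cases have dedicated closed forms in
    :func:`concentration`.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid entries must be >= 0")
    k = _rate_matrix(cl, v1, peripherals)
    w, v = np.linalg.eig(k)
    vinv = np.linalg.inv(v)
    n = k.shape[0]
    a0 = np.zeros(n)
    a0[0] = 1.0
    # amounts(t) = V diag(e^{w t}) V^{-1} a0 ; keep the central row only
    c = vinv @ a0
    row = v[0, :] * c  # coefficients of exp(w_j t) in central amount
    out = np.zeros_like(t)
    for d in doses:
        dt = t - d.time
        mask = dt >= 0
        if not np.any(mask):
            continue
        e = np.exp(np.outer(dt[mask], w))
        out[mask] += d.amount * np.real(e @ row)
    return out / v1
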