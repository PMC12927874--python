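"""Diagnostic and simulation plots (matplotlib, headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .diagnostics import VPCResult
from .pta import PTAResult

__all__ = ["plot_vpc", "plot_pta_vs_mic", "plot_npde", "plot_trace"]


def plot_vpc(vpc: VPCResult, ax=None):
    """Percentile curves of the observations against simulation prediction bands."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    b = vpc.bands
    centers = b.groupby("bin")[["axis_lo", "axis_hi"]].first().mean(axis=1)
    for pct, color in ((10, "tab:blue"), (50, "tab:red"), (90, "tab:blue")):
        sel = b[b["percentile"] == pct].set_index("bin")
        ax.fill_between(centers, sel["pi_lo"], sel["pi_hi"], alpha=0.25, color=color, lw=0)
        ax.plot(centers, sel["observed"], "-o", color=color, ms=3, label=f"obs P{pct}")
    pts = vpc.points
    ax.plot(pts[~pts.censored]["axis"], pts[~pts.censored]["pc_value"], "k.", ms=3, alpha=0.5)
    ax.plot(pts[pts.censored]["axis"], pts[pts.censored]["pc_value"], "r.", ms=4, label="censored")
    ax.set_yscale("log")
    ax.set_xlabel("time after dose (h)" if vpc.binning == "tad" else "time (h)")
    ax.set_ylabel("prediction-corrected concentration (mg/L)")
    ax.legend(fontsize=8)
    return ax


def plot_pta_vs_mic(
    result: PTAResult,
    target_label: str,
    scenario: str | None = None,
    mic_distribution: pd.DataFrame | None = None,
    ax=None,
):
    """PTA-vs-MIC curves per regimen with the 90% reference line and,
    optionally, the isolate MIC histogram overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    t = result.table
    t = t[t["target"] == target_label]
    if scenario is not None:
        t = t[t["scenario"] == scenario]
    for (dose, iv), g in t.groupby(["dose_per_kg", "interval"]):
        g = g.sort_values("mic")
        ax.plot(g["mic"], g["pta"], "-o", ms=3, label=f"{dose:g} mg/kg q{iv:g}h")
    ax.axhline(90.0, ls="--", color="k", lw=1)
    if mic_distribution is not None:
        ax2 = ax.twinx()
        counts = mic_distribution.groupby("mic").size()
        ax2.bar(counts.index, counts.values, width=counts.index * 0.15, alpha=0.3, color="gray")
        ax2.set_ylabel("isolates (n)")
    ax.set_xscale("log", base=2)
    ax.set_xlabel("MIC (mg/L)")
    ax.set_ylabel("PTA (%)")
    ax.set_title(target_label)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_npde(npde_result: dict, ax=None):
    """NPDE vs time with reference lines at 0 and +-1.96."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = npde_result["table"]
    ax.plot(t["time"], t["npde"], "k.", ms=4)
    for yv, ls in ((0, "-"), (1.96, "--"), (-1.96, "--")):
        ax.axhline(yv, color="tab:blue", ls=ls, lw=1)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("NPDE")
    return ax


def plot_trace(fit, params: list[str] | None = None):
    """SAEM convergence trace, one panel per parameter."""
    tr = fit.trace
    cols = params or [c for c in tr.columns if c != "iteration"]
    n = len(cols)
    ncol = 3
    nrow = int(np.ceil(n / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.2 * nrow), squeeze=False)
    for k, name in enumerate(cols):
        ax = axes[k // ncol][k % ncol]
        ax.plot(tr["iteration"], tr[name], lw=0.8)
        ax.axvline(fit.settings.n_burnin, color="r", ls=":", lw=0.8)
        ax.set_title(name, fontsize=8)
    for k in range(n, nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.tight_layout()
    return fig
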