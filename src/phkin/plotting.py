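"""Figure helpers for the pipeline's report stage."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_activity_profiles(estimates_df, out: str | Path) -> None:
    """Per-enzyme Vmax-vs-pH panels (slope and/or fit estimates)."""
    enzymes = sorted(estimates_df["enzyme"].unique())
    n = len(enzymes)
    ncols = min(4, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax, enzyme in zip(axes.flat, enzymes):
        sub = estimates_df[estimates_df["enzyme"] == enzyme]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("ph")
            ax.plot(grp["ph"], grp["vmax"], "o-", ms=3, label=method)
        ax.axvline(6.8, color="gray", ls="--", lw=0.6)
        ax.set_title(enzyme, fontsize=9)
        ax.set_xlabel("pH", fontsize=8)
        ax.set_ylabel("Vmax", fontsize=8)
        ax.legend(fontsize=6)
    for ax in axes.flat[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_fit_overlay(result, curves, ph: float, out: str | Path) -> None:
    """Measured vs fitted progression curves at one pH."""
    from .calibration import abs_to_conc, calibration_for

    cal = calibration_for(result.model.scheme.monitored_species)
    fig, ax = plt.subplots(figsize=(5, 3.4))
    for c in curves:
        if c.ph != ph:
            continue
        conc = abs_to_conc(c.absorbance, cal) / 0.3
        ax.plot(c.times, conc, ".", ms=2, alpha=0.5,
                label=f"DF {c.dilution_factor:g} rep {c.replicate}")
        traj = result.predict(ph, times_min=c.times,
                              dilution_factor=c.dilution_factor)
        mon = traj.concentrations[result.model.scheme.monitored_species]
        ax.plot(c.times, mon, "-", lw=1)
    ax.set_xlabel("time [min]")
    ax.set_ylabel(f"{result.model.scheme.monitored_species} [mM]")
    ax.set_title(f"{result.model.scheme.enzyme_id} at pH {ph}")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_sse_comparison(comparison: dict, out: str | Path) -> None:
    """Bar chart of the two hypothesis-layout SSEs."""
    fig, ax = plt.subplots(figsize=(3.4, 3))
    labels = ["Vmax(pH), Km global", "Km(pH), Vmax global"]
    values = [comparison["sse_vmax_varying"], comparison["sse_km_varying"]]
    ax.bar(labels, values, color=["tab:blue", "tab:orange"])
    ax.set_ylabel("SSE")
    ax.tick_params(axis="x", labelsize=7)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def plot_activity_dynamics(trace, activity: np.ndarray, enzyme_id: str,
                           out: str | Path) -> None:
    """pH trace and interpolated relative activity over time."""
    fig, ax1 = plt.subplots(figsize=(5.5, 3))
    ax1.plot(trace.times, trace.ph, color="tab:orange", lw=1, label="pH")
    ax1.set_xlabel("time [min]")
    ax1.set_ylabel("cytosolic pH", color="tab:orange")
    ax2 = ax1.twinx()
    ax2.plot(trace.times, activity, color="tab:blue", lw=1.2)
    ax2.set_ylabel(f"{enzyme_id} relative activity", color="tab:blue")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
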