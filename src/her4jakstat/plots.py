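"""Figure helpers for trajectories, interval integrals and sensitivities."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gsa import SensitivityResult
from .readouts import CASEIN_MRNA, INTERVALS
from .simulate import Trajectory

__all__ = [
    "plot_instantaneous",
    "plot_interval_bars",
    "plot_sensitivities",
    "plot_delay_sweep",
]


def plot_instantaneous(trajs: list[Trajectory], species_id: str = CASEIN_MRNA):
    """Instantaneous concentration profiles, one line per NRG dose."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for tr in trajs:
        ax.plot(tr.times, tr.get(species_id), label=f"{tr.dose:g} nM NRG")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"[{species_id}] (nM)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_interval_bars(summary: pd.DataFrame):
    """Interval-integrated beta-casein with ensemble error bars.

    ``summary`` columns: interval, dose_nM, mean, sd.
    """
    intervals = [f"{a:g}-{b:g}h" for a, b in INTERVALS]
    fig, axes = plt.subplots(1, len(intervals), figsize=(9, 3.2), sharey=False)
    for ax, iv in zip(np.atleast_1d(axes), intervals):
        sub = summary[summary["interval"] == iv]
        x = np.arange(len(sub))
        ax.bar(x, sub["mean"], yerr=sub["sd"], capsize=3)
        ax.set_xticks(x)
        ax.set_xticklabels([f"{d:g}" for d in sub["dose_nM"]])
        ax.set_title(iv, fontsize=9)
        ax.set_xlabel("NRG (nM)")
    np.atleast_1d(axes)[0].set_ylabel("integrated mRNA (nM·h)")
    fig.tight_layout()
    return fig


def plot_sensitivities(result: SensitivityResult, species_ids: list[str], top: int = 10):
    """Twin panels (species initial amounts | rate constants) of S1 and ST."""
    rows = sorted(
        zip(result.parameter_ids, result.S1, result.ST),
        key=lambda r: -max(r[2], 0.0),
    )
    species = [r for r in rows if r[0] in species_ids][:top]
    params = [r for r in rows if r[0] not in species_ids][:top]
    fig, axes = plt.subplots(1, 2, figsize=(10, 3.6))
    for ax, data, title in zip(axes, (species, params), ("species", "parameters")):
        if not data:
            ax.set_visible(False)
            continue
        ids = [r[0] for r in data]
        x = np.arange(len(ids))
        ax.bar(x - 0.2, [max(r[1], 0) for r in data], width=0.4, label="S1")
        ax.bar(x + 0.2, [max(r[2], 0) for r in data], width=0.4, label="ST")
        ax.set_xticks(x)
        ax.set_xticklabels(ids, rotation=45, ha="right", fontsize=7)
        ax.set_title(f"{result.output_name}: {title}", fontsize=9)
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_delay_sweep(sweep: pd.DataFrame):
    """Transcription delay vs transport-rate multiplier (one line per rate)."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for pid, sub in sweep.groupby("parameter_id"):
        sub = sub.sort_values("multiplier")
        ax.plot(sub["multiplier"], sub["delay_h"], marker="o", label=pid)
    ax.set_xscale("log")
    ax.set_xlabel("rate multiplier (x baseline)")
    ax.set_ylabel("STAT5 dimer to mRNA peak delay (h)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig
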