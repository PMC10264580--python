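"""Figures: group mean +/- SEM latency-change trajectories with stars."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .components import MEASURES

__all__ = ["plot_group_trajectories", "plot_average_trace"]


def plot_group_trajectories(
    endpoints: pd.DataFrame,
    stats_results: pd.DataFrame | None,
    path: str | os.PathLike,
    grouping: str = "group_stratified",
    measures=None,
) -> str:
    """One panel per latency measure: mean +/- SEM percent change by group
    over days, annotated with post-hoc significance stars per timepoint."""
    measures = list(measures) if measures is not None else [
        m for m in MEASURES if m in set(endpoints["measure"])
    ]
    ncol = 3
    nrow = int(np.ceil(len(measures) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(4.2 * ncol, 3.2 * nrow), squeeze=False, sharex=True
    )
    groups = [g for g in endpoints[grouping].unique() if g != "unclassifiable"]
    for k, measure in enumerate(measures):
        ax = axes[k // ncol][k % ncol]
        sub = endpoints[endpoints["measure"] == measure]
        for g in groups:
            cell = sub[sub[grouping] == g]
            agg = cell.groupby("day")["pct_change"].agg(["mean", "sem"]).reset_index()
            ax.errorbar(
                agg["day"], agg["mean"], yerr=agg["sem"], marker="o", capsize=2, label=g
            )
        if stats_results is not None and not stats_results.empty:
            sig = stats_results[
                (stats_results["measure"] == measure)
                & (stats_results["test"] == "dunn")
                & stats_results["significant"]
            ]
            for day, day_rows in sig.groupby("day"):
                txt = " ".join(day_rows["stars"])
                ymax = sub[sub["day"] == day]["pct_change"].max()
                if np.isfinite(ymax):
                    ax.annotate(
                        txt, (day, ymax), textcoords="offset points", xytext=(0, 6),
                        ha="center", fontsize=8,
                    )
        ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
        ax.set_title(measure)
        ax.set_xlabel("day")
        ax.set_ylabel("latency change (%)")
    for k in range(len(measures), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_average_trace(avg, marks=None, path: str | os.PathLike = "average.png") -> str:
    """Diagnostic plot of one average trace with its P1/N1/P2 marks."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(avg.times_ms, avg.samples, lw=1.0, color="k")
    if marks is not None:
        for comp, color in [("P1", "tab:blue"), ("N1", "tab:red"), ("P2", "tab:green")]:
            lat = marks.latency(comp)
            if lat is not None:
                idx = int(round(lat / 1000.0 * avg.sampling_rate))
                ax.plot(lat, avg.samples[idx], "o", color=color, label=comp)
        ax.legend(fontsize=8)
    ax.set_xlabel("time from flash (ms)")
    ax.set_ylabel("amplitude (uV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
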