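"""Cosmetic plotting helpers for time-course and dose-series figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_timecourse", "plot_dose_series"]


def plot_timecourse(table: pd.DataFrame, path: str | Path, errorbar: str = "sd") -> Path:
    """Mean ± SD/SEM vs timepoint, one panel per metric; saves SVG/PNG."""
    metrics = sorted(table["metric"].unique())
    fig, axes = plt.subplots(1, max(len(metrics), 1), figsize=(4 * max(len(metrics), 1), 3.2))
    if len(metrics) <= 1:
        axes = [axes]
    for ax, metric in zip(axes, metrics):
        sub = table[table["metric"] == metric]
        for cond, grp in sub.groupby("condition_id"):
            grp = grp.sort_values("timepoint_h")
            ax.errorbar(
                grp["timepoint_h"], grp["mean"], yerr=grp[errorbar],
                marker="o", capsize=3, label=str(cond),
            )
        ax.set_xlabel("time after axotomy (h)")
        ax.set_ylabel(metric)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_dose_series(summary: pd.DataFrame, doses: dict, metric: str, path: str | Path) -> Path:
    """Mean ± SD vs dose for one metric; saves SVG/PNG."""
    sub = summary[summary["metric"] == metric].copy()
    sub["dose"] = sub["condition_id"].map(doses)
    sub = sub.dropna(subset=["dose"]).sort_values("dose")
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.errorbar(sub["dose"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3)
    ax.set_xlabel("dose")
    ax.set_ylabel(metric)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
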