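"""Plotting helpers for GTA profiles and quality distributions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_gta_profiles", "plot_quality_distributions"]


def plot_gta_profiles(profiles: pd.DataFrame, cohort: pd.DataFrame,
                      out_path, metrics=None) -> None:
    """Group-median GTA parameters with interquartile bands across thresholds."""
    merged = profiles.merge(cohort[["subject_id", "group"]], on="subject_id")
    metrics = metrics or sorted(profiles["metric"].unique())
    ncol = 3
    nrow = int(np.ceil(len(metrics) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow),
                             squeeze=False)
    for ax, metric in zip(axes.ravel(), metrics):
        for group, sub in merged[merged["metric"] == metric].groupby("group"):
            q = sub.groupby("threshold")["value"].quantile([0.25, 0.5, 0.75]).unstack()
            ax.plot(q.index, q[0.5], label=group)
            ax.fill_between(q.index, q[0.25], q[0.75], alpha=0.25)
        ax.set_title(metric)
        ax.set_xlabel("threshold")
    for ax in axes.ravel()[len(metrics):]:
        ax.axis("off")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_quality_distributions(cohort: pd.DataFrame, out_path) -> None:
    """Per-group box plots of SNR, tSNR and CNR."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, metric in zip(axes, ("snr", "tsnr", "cnr")):
        data = [sub[metric].to_numpy() for _, sub in cohort.groupby("group")]
        ax.boxplot(data, tick_labels=[g for g, _ in cohort.groupby("group")])
        ax.set_title(metric.upper() if metric != "tsnr" else "tSNR")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
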