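"""Figure-style exports: severity heatmaps and interval plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pawtherm.scoring import HeatmapResult, SeverityLevel

__all__ = ["plot_severity_heatmap", "plot_interval_summary", "plot_auc_bars"]

_SEVERITY_COLORS = ["#1f3d99", "#f2f2f2", "#f5c542", "#c2302a"]  # absent..severe


def plot_severity_heatmap(result: HeatmapResult, title: str, path: str | Path) -> Path:
    """Render the mice x paws severity matrix in the four-level palette."""
    mat = result.labels.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4, 0.35 * mat.shape[0] + 1.2))
    cmap = matplotlib.colors.ListedColormap(_SEVERITY_COLORS)
    ax.imshow(mat, cmap=cmap, vmin=-0.5, vmax=3.5, aspect="auto")
    ax.set_xticks(range(mat.shape[1]), result.labels.columns)
    labels = [
        f"{m} *" if flag else str(m)
        for m, flag in result.moderate_severe.items()
    ]
    ax.set_yticks(range(mat.shape[0]), labels, fontsize=7)
    ax.set_title(f"{title} (* = moderate-severe, all 4 joints)", fontsize=9)
    handles = [
        plt.Rectangle((0, 0), 1, 1, color=c)
        for c in _SEVERITY_COLORS
    ]
    ax.legend(
        handles,
        [str(SeverityLevel(i)) for i in range(4)],
        bbox_to_anchor=(1.02, 1),
        loc="upper left",
        fontsize=7,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_interval_summary(summary: pd.DataFrame, endpoint: str, path: str | Path) -> Path:
    """Mean +/- SD per group over study days (interval plot)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for group, sub in summary.groupby("group"):
        sub = sub.sort_values("day")
        ax.errorbar(
            sub["day"], sub["mean"], yerr=sub["sd"], marker="o", capsize=3, label=group
        )
    ax.set_xlabel("study day")
    ax.set_ylabel(endpoint)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_auc_bars(auc_table: pd.DataFrame, endpoint: str, path: str | Path) -> Path:
    """Group mean +/- SD of per-mouse AUCs for one endpoint."""
    sub = auc_table[auc_table["endpoint"] == endpoint]
    groups = sorted(sub["group"].unique())
    means = [sub.loc[sub["group"] == g, "auc"].mean() for g in groups]
    sds = [sub.loc[sub["group"] == g, "auc"].std(ddof=1) for g in groups]
    fig, ax = plt.subplots(figsize=(4, 3.2))
    ax.bar(groups, means, yerr=np.nan_to_num(sds), capsize=4, color="#888")
    ax.set_ylabel(f"AUC of {endpoint} (units x days)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
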