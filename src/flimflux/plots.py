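"""Optional plot outputs: group bar charts, lifetime histograms, KDE curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .stats import kde_normalized

__all__ = ["plot_group_bars", "plot_tm_histogram", "plot_kde"]


def plot_group_bars(summary: pd.DataFrame, path, value: str = "mean",
                    err: str = "sem", label: str = "tm (ps)") -> Path:
    """Bar graph of group summaries (one bar per row, SEM error bars)."""
    fig, ax = plt.subplots(figsize=(1.2 * len(summary) + 2, 4))
    keys = [c for c in summary.columns if c not in ("n", "mean", "median", "sd", "sem")]
    names = summary[keys].astype(str).agg("/".join, axis=1)
    ax.bar(names, summary[value], yerr=summary[err], capsize=4)
    ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_tm_histogram(table: pd.DataFrame, path, value: str = "tm_ps",
                      group: str = "group", bins: int = 40) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in table.groupby(group, observed=True):
        ax.hist(sub[value].dropna(), bins=bins, alpha=0.5, label=str(g))
    ax.set_xlabel(value)
    ax.set_ylabel("frequency")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_kde(table: pd.DataFrame, path, value: str = "tm_ps",
             group: str = "group", bandwidth: float | None = None) -> Path:
    """Sample-size-normalized KDE curves (each integrates to 1)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for g, sub in table.groupby(group, observed=True):
        x, dens = kde_normalized(sub[value].dropna().to_numpy(), bandwidth=bandwidth)
        ax.plot(x, dens, label=str(g))
    ax.set_xlabel(value)
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
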