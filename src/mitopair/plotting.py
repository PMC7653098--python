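"""Optional matplotlib figures for cohort reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import pandas as pd


def plot_gene_rates(rates: pd.DataFrame, path=None, min_count: int = 1):
    """Barplot of per-gene variant counts with the rate/kb as a line."""
    df = rates[rates["count"] >= min_count].reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(df)), 4))
    ax.bar(df["gene"], df["count"], color="steelblue")
    ax.set_ylabel("variants")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["gene"], rotation=90, fontsize=7)
    ax2 = ax.twinx()
    ax2.plot(df["gene"], df["rate_per_kb"], color="black", lw=1)
    ax2.set_ylabel("variants / kb")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_km(curves: dict, path=None):
    """Step plot of per-group Kaplan-Meier survival functions."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for group, df in curves.items():
        ax.step(df["time"], df["survival"], where="post", label=group)
    ax.set_xlabel("months")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
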