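"""Basic diagnostic figures (line/bar plots of sweep outputs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_donation_fractions", "plot_ccc_histograms"]


def plot_donation_fractions(timeseries: pd.DataFrame, path: str | Path) -> None:
    """One line per condition: replicate-mean donation fraction vs generation."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for (w, cost), sub in timeseries.groupby(["w", "inflicted_cost"]):
        mean = sub.groupby("generation")["donation_fraction"].mean()
        ax.plot(mean.index, mean.values, label=f"w={w}, cost={cost}", lw=0.8)
    ax.set_xlabel("generation")
    ax.set_ylabel("donation fraction")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ccc_histograms(histograms: pd.DataFrame, path: str | Path) -> None:
    """Bar panels of pooled final-population CCC counts per condition."""
    conditions = list(histograms.groupby(["w", "inflicted_cost"]).groups)
    n = max(len(conditions), 1)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3), squeeze=False)
    for ax, (w, cost) in zip(axes[0], conditions):
        sub = histograms[(histograms["w"] == w) & (histograms["inflicted_cost"] == cost)]
        width = (sub["bin_right"] - sub["bin_left"]).iloc[0]
        ax.bar(sub["bin_left"], sub["count"], width=width, align="edge",
               edgecolor="black", linewidth=0.4)
        ax.set_title(f"w={w}, cost={cost}", fontsize=9)
        ax.set_xlabel("CCC")
    axes[0][0].set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
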