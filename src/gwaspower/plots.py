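"""Plain matplotlib plots of power results.

Two views: mean power per reference-panel MAF stratum across scenarios,
and the histogram of SNPs by cross-panel frequency difference colored by
the mean power change per bin.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .aggregation import GainByDifference, PowerResult

__all__ = ["plot_power_by_maf", "plot_gain_histogram"]


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_power_by_maf(results: Mapping[str, PowerResult], path: str | Path) -> None:
    """Bar chart of mean power per MAF stratum, one group per scenario."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(7, 4))
    labels = None
    n = len(results)
    for k, (name, result) in enumerate(results.items()):
        summary = result.stratum_summary
        if labels is None:
            labels = list(summary["stratum"])
        x = [i + (k - (n - 1) / 2) * 0.8 / n for i in range(len(summary))]
        ax.bar(x, summary["mean_power"], width=0.8 / n, label=name)
    ax.set_xticks(range(len(labels or [])))
    ax.set_xticklabels(labels or [], rotation=30, ha="right")
    ax.set_ylabel("mean power")
    ax.set_xlabel("MAF stratum (reference panel)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_gain_histogram(gain: GainByDifference, path: str | Path) -> None:
    """SNP counts by frequency-difference bin, colored by mean power change."""
    plt = _axes()
    import matplotlib.cm as cm
    import matplotlib.colors as mcolors

    bins = gain.bins
    norm = mcolors.TwoSlopeNorm(
        vcenter=0.0,
        vmin=min(-1e-6, float(bins["mean_dpower"].min())),
        vmax=max(1e-6, float(bins["mean_dpower"].max())),
    )
    cmap = cm.coolwarm
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        bins["bin_lo"],
        bins["count"],
        width=gain.bin_width,
        align="edge",
        color=[cmap(norm(v)) for v in bins["mean_dpower"]],
        edgecolor="black",
        linewidth=0.3,
    )
    ax.set_xlabel("allele frequency difference (alt - ref, anchored minor allele)")
    ax.set_ylabel("SNP count")
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, label="mean Δpower")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
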