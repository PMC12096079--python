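"""Optional figures: metagene profiles and expression scatter plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .comparative_analysis import MetageneProfile


def plot_metagene(profiles: Mapping[str, MetageneProfile], path: str | Path) -> None:
    """Line plot of per-bin modified/total motif ratios along the CDS."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, profile in profiles.items():
        x = (np.arange(profile.n_bins) + 0.5) / profile.n_bins
        ax.plot(x, profile.bins, marker="o", label=label)
    ax.set_xlabel("relative CDS position (5' → 3')")
    ax.set_ylabel("modified / total motifs")
    ax.set_ylim(bottom=0)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_expression_scatter(
    ctrl_log2: pd.Series,
    stress_log2: pd.Series,
    path: str | Path,
    r: float | None = None,
    de_threshold: float = 1.0,
    highlight: set[str] | None = None,
) -> None:
    """log2-RPKM scatter with +/- de_threshold fold-change guide lines."""
    shared = ctrl_log2.index.intersection(stress_log2.index)
    x, y = ctrl_log2.loc[shared], stress_log2.loc[shared]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=6, color="0.6", linewidths=0)
    if highlight:
        hi = [g for g in shared if g in highlight]
        ax.scatter(x.loc[hi], y.loc[hi], s=8, color="tab:blue", linewidths=0)
    lo = min(x.min(), y.min())
    hi_ = max(x.max(), y.max())
    grid = np.array([lo, hi_])
    ax.plot(grid, grid, color="k", lw=0.8)
    for off in (de_threshold, -de_threshold):
        ax.plot(grid, grid + off, color="k", lw=0.8, ls="--")
    ax.set_xlabel("control log2 RPKM")
    ax.set_ylabel("stress log2 RPKM")
    if r is not None:
        ax.set_title(f"r = {r:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
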