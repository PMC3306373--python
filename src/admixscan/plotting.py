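"""Genome-track and risk-curve figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scan import LOD_SUGGESTIVE, Z_SIGNIFICANT


def plot_scan(table: pd.DataFrame, path) -> None:
    """Two-panel genome track: per-locus LOD and case-control Z."""
    fig, axes = plt.subplots(2, 1, figsize=(11, 5), sharex=True)
    offset, ticks, tick_pos = 0.0, [], []
    for chrom, sub in table.groupby("chromosome", sort=True):
        x = sub["genetic_pos"].to_numpy() + offset
        axes[0].plot(x, sub["lod"], color="firebrick", lw=0.8)
        axes[1].plot(x, sub["z"], color="steelblue", lw=0.8)
        ticks.append(str(chrom))
        tick_pos.append(offset + sub["genetic_pos"].max() / 2)
        offset += sub["genetic_pos"].max() + 0.1
    axes[0].axhline(LOD_SUGGESTIVE, ls="--", color="grey", lw=0.7)
    axes[0].set_ylabel("LOD")
    for s in (Z_SIGNIFICANT, -Z_SIGNIFICANT):
        axes[1].axhline(s, ls="--", color="grey", lw=0.7)
    axes[1].set_ylabel("Z")
    axes[1].set_xticks(tick_pos, ticks)
    axes[1].set_xlabel("chromosome")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk_curve(curve: pd.DataFrame, path) -> None:
    """Spline odds-ratio curve over ancestry with its confidence band."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = 100 * np.asarray(curve["ancestry"])
    ax.fill_between(x, curve["ci_low"], curve["ci_high"], alpha=0.25, color="grey")
    ax.plot(x, curve["odds_ratio"], color="black")
    ax.axhline(1.0, ls=":", color="grey", lw=0.7)
    ax.set_xlabel("African ancestry (%)")
    ax.set_ylabel("odds ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
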