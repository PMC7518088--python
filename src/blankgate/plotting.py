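"""Matplotlib helpers for the QC results (ordination scatter and
per-volume boxplots)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import Metadata

__all__ = ["plot_nmds", "plot_by_volume"]


def plot_nmds(nmds_result, labels: pd.Series, permanova=None, ax=None):
    """Scatter the first two NMDS axes coloured by group label."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    coords = nmds_result.coordinates
    for group, color in zip(sorted(labels.unique()), ("#1f4e79", "#9dc3e6", "#c55a11")):
        idx = labels.index[labels == group]
        ax.scatter(coords.loc[idx, coords.columns[0]],
                   coords.loc[idx, coords.columns[1]],
                   label=str(group), color=color, edgecolor="k", s=45, alpha=0.85)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    title = f"NMDS (stress = {nmds_result.stress:.3f})"
    if permanova is not None:
        title += (f"\nPERMANOVA F = {permanova.pseudo_F:.2f}, "
                  f"p = {permanova.p_value:.3f}")
    ax.set_title(title)
    ax.legend(title="detection")
    return ax


def plot_by_volume(values: pd.Series, metadata: Metadata, ylabel: str = "",
                   hline=None, ax=None):
    """Boxplots of a per-sample statistic grouped by filtered volume; the
    0 mL bin holds the blanks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    vols = pd.Series({sid: metadata.volume(sid) for sid in values.index
                      if sid in metadata})
    order = sorted(vols.unique())
    data = [values[vols.index[vols == v]].to_numpy(dtype=float) for v in order]
    ax.boxplot(data, tick_labels=[str(v) for v in order], whis=1.5)
    if hline is not None:
        ax.axhline(hline, color="crimson", ls="--", lw=1,
                   label=f"threshold = {hline:.3g}")
        ax.legend()
    ax.set_xlabel("filtered volume (mL)")
    ax.set_ylabel(ylabel)
    return ax
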