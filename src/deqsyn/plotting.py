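"""Basic isobologram and Bliss heatmap plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bliss import BlissGrid
from .isobologram import IsobologramResult


def plot_isobologram(result: IsobologramResult, ax=None):
    """Normalized isobologram: additivity line x + y = 1, one point per ratio.

    Axes are fractional contributions (contribution / alone EC50), so the
    single-agent intercepts sit at 1.0 and a point's coordinate sum is its
    CI. Points below the dashed line indicate synergy.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0, 1], [1, 0], "k--", lw=1, label="additivity")
    for r in result.ratios.values():
        x, y = r.isobole_point
        ax.plot(x, y, "o", ms=6, label=f"{r.ratio_label} (CI={r.ci:.2f})")
    ax.set_xlabel(f"{result.drug_a} fractional EC50")
    ax.set_ylabel(f"{result.drug_b} fractional EC50")
    ax.set_xlim(0, 1.1)
    ax.set_ylim(0, 1.1)
    ax.legend(fontsize=7)
    return ax


def plot_viability_heatmap(grid: BlissGrid, ax=None):
    """Green-to-red viability heatmap over the dose grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        grid.viability.T, origin="lower", cmap="RdYlGn", vmin=0, vmax=1, aspect="auto"
    )
    _dose_axes(grid, ax)
    ax.figure.colorbar(im, ax=ax, label="viability")
    return ax


def plot_bliss_heatmap(grid: BlissGrid, ax=None):
    """Bliss Index heatmap; cells below the synergy threshold are outlined."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        grid.bliss_index.T, origin="lower", cmap="coolwarm", vmin=0.5, vmax=1.5,
        aspect="auto",
    )
    ii, jj = np.where(grid.synergy_mask)
    ax.plot(ii, jj, "k.", ms=3)
    _dose_axes(grid, ax)
    ax.figure.colorbar(im, ax=ax, label=f"Bliss Index (synergy < {grid.threshold})")
    return ax


def _dose_axes(grid: BlissGrid, ax):
    ax.set_xticks(range(len(grid.doses_a)))
    ax.set_xticklabels([f"{d:.2f}" for d in grid.doses_a], rotation=90, fontsize=6)
    ax.set_yticks(range(len(grid.doses_b)))
    ax.set_yticklabels([f"{d:.2f}" for d in grid.doses_b], fontsize=6)
    ax.set_xlabel(f"log10 [{grid.drug_a}] (M)")
    ax.set_ylabel(f"log10 [{grid.drug_b}] (M)")
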