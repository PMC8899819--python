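"""Figures: information-footprint track and enrichment heat maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .footprint import EnrichmentMap, FootprintResult


def plot_footprint(
    footprint: FootprintResult, path: str | Path | None = None, log_scale: bool = False
):
    """Bar track of per-position mutual information (bits)."""
    fig, ax = plt.subplots(figsize=(12, 3))
    ax.bar(footprint.positions, footprint.mi_bits.to_numpy(), width=1.0, color="#2b6cb0")
    ax.set_xlabel("position (P-coordinate)")
    ax.set_ylabel("mutual information (bits)")
    if log_scale:
        ax.set_yscale("log")
    ax.set_title("information footprint")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_enrichment_heatmap(emap: EnrichmentMap, path: str | Path | None = None):
    """Position x base heat map of log2 enrichment ratios (blue enriched,
    orange depleted)."""
    data = emap.log2_ratio.T  # bases as rows
    fig, ax = plt.subplots(figsize=(12, 2.2))
    vmax = max(abs(data.to_numpy()).max(), 1e-9)
    im = ax.imshow(
        data.to_numpy(),
        aspect="auto",
        cmap="RdYlBu",
        vmin=-vmax,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_yticks(range(len(data.index)), data.index)
    step = max(len(data.columns) // 12, 1)
    ax.set_xticks(range(0, len(data.columns), step))
    ax.set_xticklabels([f"P{p}" for p in data.columns[::step]], rotation=90, fontsize=7)
    ax.set_title(f"enrichment vs unsorted: {emap.bin_label} bin")
    fig.colorbar(im, ax=ax, label="log2 ratio")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
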