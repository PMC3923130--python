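"""Stacked-bar composition and per-stage index profile plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_composition(composition: pd.DataFrame, path) -> None:
    """Stacked bars: expression share of each divergence bin per stage."""
    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = None
    labels = {"bin1": "low divergence", "bin2": "medium", "bin3": "high divergence"}
    for col in composition.columns:
        vals = composition[col].to_numpy()
        ax.bar(composition.index, vals, bottom=bottom, label=labels.get(col, col))
        bottom = vals if bottom is None else bottom + vals
    ax.set_ylabel("fraction of microRNA expression")
    ax.set_xlabel("developmental stage")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_stage_profiles(table: pd.DataFrame, path) -> None:
    """TAI and TDI profiles across stages with bootstrap error bars."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, idx in zip(axes, ("tai", "tdi")):
        ax.errorbar(table.index, table[idx], yerr=table[f"{idx}_sd"],
                    marker="o", capsize=3)
        ax.set_ylabel(idx.upper())
        ax.set_xlabel("stage")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
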