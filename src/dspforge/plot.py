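"""Minimal check plots: clustered heatmap, volcano and forest plots."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _pyplot():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def heatmap(scaled: pd.DataFrame, order: list[int] | None = None,
            path: str | None = None):
    """Relative-expression heatmap with ROIs in dendrogram order."""
    plt = _pyplot()
    data = scaled.iloc[order] if order is not None else scaled
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(data.to_numpy().T, aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xlabel("ROI")
    ax.set_ylabel("probe")
    ax.set_yticks(range(len(data.columns)))
    ax.set_yticklabels(data.columns, fontsize=4)
    fig.colorbar(im, ax=ax, label="z-score (log2)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def volcano(de: pd.DataFrame, alpha: float = 0.05, path: str | None = None):
    """Effect vs -log10 adjusted p per probe for one comparison."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 4))
    neglog = -np.log10(de["p_adj"].astype(float).clip(lower=1e-300))
    sig = de["p_adj"] < alpha
    ax.scatter(de.loc[~sig, "effect"], neglog[~sig], s=12, c="grey")
    ax.scatter(de.loc[sig, "effect"], neglog[sig], s=12, c="crimson")
    for _, row in de[sig].iterrows():
        ax.annotate(row["probe_id"], (row["effect"], -np.log10(row["p_adj"])),
                    fontsize=6)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.set_xlabel("effect (log2 difference)")
    ax.set_ylabel("-log10 adjusted p")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def forest(cox: pd.DataFrame, path: str | None = None):
    """Hazard ratios with 95% CIs, ranked as returned by the screen."""
    plt = _pyplot()
    fig, ax = plt.subplots(figsize=(5, 0.25 * max(len(cox), 4) + 1))
    y = np.arange(len(cox))[::-1]
    ax.errorbar(cox["hr"], y,
                xerr=[cox["hr"] - cox["ci_low"], cox["ci_high"] - cox["hr"]],
                fmt="o", ms=4, capsize=2, lw=0.8)
    ax.axvline(1.0, ls="--", lw=0.8, c="k")
    ax.set_yticks(y)
    ax.set_yticklabels(cox["probe_id"], fontsize=6)
    ax.set_xscale("log")
    ax.set_xlabel("hazard ratio (95% CI)")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
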