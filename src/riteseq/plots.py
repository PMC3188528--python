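"""Diagnostic figures: per-clone ratio bars and concordance scatterplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .quantify import _CORR_PAIRS, RATIO_COLUMNS

__all__ = ["ratio_bar_figure", "concordance_figure", "save_figures"]

_CONTROL_COLORS = {"CONTROL_HA": "#1f77b4", "CONTROL_T7": "#d62728"}


def ratio_bar_figure(records: pd.DataFrame, included_only: bool = True):
    """Mean T7/HA ratio per clone, sorted ascending, controls highlighted.

    Control strains are drawn regardless of their inclusion flag so they
    frame the dynamic range of the screen.
    """
    df = records.copy()
    if included_only:
        df = df[df["included"] | df["status"].str.startswith("CONTROL")]
    df = df[np.isfinite(df["mean_ratio"])].sort_values("mean_ratio")
    colors = [_CONTROL_COLORS.get(s, "#7f7f7f") for s in df["status"]]
    fig, ax = plt.subplots(figsize=(max(6, 0.25 * len(df)), 4))
    ax.bar(range(len(df)), df["mean_ratio"], color=colors)
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["gene"], rotation=90, fontsize=7)
    ax.set_ylabel("mean T7/HA ratio")
    ax.set_title("Histone turnover per clone (controls colored)")
    fig.tight_layout()
    return fig


def concordance_figure(records: pd.DataFrame):
    """2x2 scatter of UpTag vs DownTag and t1 vs t3 ratios with Pearson r."""
    from scipy import stats

    fig, axes = plt.subplots(2, 2, figsize=(8, 8))
    for ax, (name, (a, b)) in zip(axes.ravel(), _CORR_PAIRS.items()):
        sub = records[[a, b]].replace([np.inf, -np.inf], np.nan).dropna()
        ax.scatter(sub[a], sub[b], s=12, alpha=0.7)
        if len(sub) >= 3:
            r = stats.pearsonr(sub[a], sub[b]).statistic
            ax.set_title(f"{name} (r = {r:.2f})", fontsize=9)
        else:
            ax.set_title(f"{name} (n < 3)", fontsize=9)
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    fig.tight_layout()
    return fig


def save_figures(records: pd.DataFrame, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, fig in [
        ("ratio_bars.png", ratio_bar_figure(records)),
        ("concordance.png", concordance_figure(records)),
    ]:
        p = out / name
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths
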