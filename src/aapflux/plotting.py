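"""Diagnostic figures: light-effect forest plot and dbRDA biplot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .community import DbRDAResult


def plot_light_effects(effects: pd.DataFrame, ax=None):
    """Forest plot of percent dark-vs-IR differences with 95% CIs.

    ``effects`` is the table from
    :func:`aapflux.pipeline.light_effect_summaries`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.6 * len(effects) + 1))
    y = np.arange(len(effects))[::-1]
    signed = np.where(
        effects.direction.str.contains("dark"), -1.0, 1.0
    ) * effects.percent_difference
    lo = np.where(effects.direction.str.contains("dark"), -1.0, 1.0)
    ax.errorbar(
        signed,
        y,
        xerr=np.vstack(
            [
                np.abs(signed - lo * effects.ci_high),
                np.abs(lo * effects.ci_low - signed),
            ]
        ),
        fmt="o",
        color="k",
        capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(effects.analyte)
    ax.set_xlabel("% difference (negative: higher in dark)")
    return ax


def plot_dbrda(result: DbRDAResult, ax=None, arrow_scale: float | None = None):
    """dbRDA ordination: sample scores plus predictor arrows."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sc = result.scores
    ax.scatter(sc[:, 0], sc[:, 1] if sc.shape[1] > 1 else np.zeros(len(sc)),
               s=20, color="tab:blue")
    if arrow_scale is None:
        arrow_scale = 0.8 * np.abs(sc[:, 0]).max()
    for name, row in result.biplot.iterrows():
        dx = row.iloc[0] * arrow_scale
        dy = (row.iloc[1] if len(row) > 1 else 0.0) * arrow_scale
        ax.annotate(
            "", xy=(dx, dy), xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="k"),
        )
        ax.text(dx * 1.05, dy * 1.05, str(name), fontsize=9)
    tot = result.eigenvalues.sum()
    ax.set_xlabel(f"dbRDA1 ({100 * result.eigenvalues[0] / tot:.0f}%)")
    if sc.shape[1] > 1:
        ax.set_ylabel(f"dbRDA2 ({100 * result.eigenvalues[1] / tot:.0f}%)")
    return ax
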