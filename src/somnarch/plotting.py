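"""Figure conveniences mirroring the study's panel layouts.

Figures are conveniences, not contracts: every quantity plotted here is
also written to a metric table by the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_GROUP_COLORS = {"WT": "black", "MUT": "tab:red"}


def _groups(df):
    for (sex, genotype), g in df.groupby(["sex", "genotype"]):
        yield sex, genotype, g


def plot_time_in_state(df: pd.DataFrame, state: str, phase: str, ax=None):
    """Per-animal scatter with group mean bars, light vs dark side by side."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    sub = df[(df["state"] == state) & (df["phase"] == phase)]
    order = [(p, s, g) for p in ("light", "dark") for s in ("M", "F") for g in ("WT", "MUT")]
    for x, (period, sex, genotype) in enumerate(order):
        vals = sub[(sub["period"] == period) & (sub["sex"] == sex)
                   & (sub["genotype"] == genotype)]["pct_trt"].to_numpy()
        if vals.size == 0:
            continue
        color = _GROUP_COLORS[genotype]
        face = color if sex == "M" else "white"
        ax.bar(x, vals.mean(), width=0.7, color="0.85", zorder=1)
        ax.scatter(np.full(vals.size, x), vals, s=18, zorder=2,
                   facecolors=face, edgecolors=color)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels([f"{p[0].upper()}\n{s}-{g}" for p, s, g in order], fontsize=7)
    ax.set_ylabel(f"{state} (% TRT)")
    ax.set_title(f"{phase} {state}")
    return ax


def plot_group_spectra(freqs, group_cis: dict, ax=None, fmax: float = 20.0):
    """Mean relative spectra with shaded 95% CIs per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    mask = freqs <= fmax
    for label, (mean, lo, hi) in group_cis.items():
        color = _GROUP_COLORS.get(label.split("/")[-1], None)
        ax.plot(freqs[mask], mean[mask], label=label, color=color)
        ax.fill_between(freqs[mask], lo[mask], hi[mask], alpha=0.25, color=color)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("relative power (%)")
    ax.legend(fontsize=7)
    return ax


def plot_pressure(pressure: pd.DataFrame, ax=None):
    """Hourly normalized NREM delta power, group mean with SEM bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 3.2))
    for (sex, genotype), g in pressure.groupby(["sex", "genotype"]):
        agg = g.groupby("hour")["norm_delta"].agg(["mean", "sem"])
        color = _GROUP_COLORS[genotype]
        ls = "-" if sex == "M" else ":"
        ax.errorbar(agg.index, agg["mean"], yerr=agg["sem"], color=color,
                    linestyle=ls, label=f"{sex}/{genotype}", capsize=2)
    ax.axhline(1.0, color="0.6", lw=0.8)
    ax.set_xlabel("hour from recording start")
    ax.set_ylabel("normalized NREM delta")
    ax.legend(fontsize=7)
    return ax


__all__ = ["plot_time_in_state", "plot_group_spectra", "plot_pressure"]
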