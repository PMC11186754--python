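"""Plots: per-sample mutational-spectrum bars and the cohort bubble chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .spectrum import SUBSTITUTION_CLASSES, SpectrumCurve

_CLASS_COLORS = plt.colormaps["viridis"](np.linspace(0.05, 0.95, len(SUBSTITUTION_CLASSES)))


def plot_spectrum(curve: SpectrumCurve, ax=None):
    """Stacked bars of mutations/Mb per substitution class along the VAF grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottom = np.zeros(len(curve.vaf_grid))
    width = 0.8 * min(np.diff(curve.vaf_grid), default=0.05)
    for cls, color in zip(SUBSTITUTION_CLASSES, _CLASS_COLORS):
        dens = curve.density(cls)
        ax.bar(curve.vaf_grid, dens, bottom=bottom, width=width, color=color, label=cls)
        bottom += dens
    ax.set_xlabel("minimal VAF")
    ax.set_ylabel("mutations / Mb")
    ax.set_title(curve.sample)
    ax.legend(fontsize=7, ncol=2)
    return ax


def plot_cohort_dynamics(table: pd.DataFrame, ax=None):
    """Bubble chart of fraction lost/gained per patient (rows of the cohort table)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 0.5 * max(len(table), 4) + 1))
    y = np.arange(len(table))
    for x, col in ((0, "fraction_lost"), (1, "fraction_gained")):
        vals = table[col].to_numpy(dtype=float)
        ax.scatter(
            np.full_like(y, x, dtype=float), y,
            s=20 + 600 * vals, c=vals, cmap="viridis", vmin=0, vmax=1,
        )
    ax.set_xticks([0, 1], ["fraction lost", "fraction gained"])
    ax.set_yticks(y, table["patient_id"])
    ax.set_xlim(-0.5, 1.5)
    ax.invert_yaxis()
    return ax
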