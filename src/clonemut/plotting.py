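"""Convenience plots: 96-channel spectrum bars and rainfall scatter."""

from __future__ import annotations

import numpy as np

from .channels import CHANNELS, CLASSES
from .types import Spectrum96

_CLASS_COLORS = {
    "C>A": "#03bcee", "C>G": "#010101", "C>T": "#e32926",
    "T>A": "#cac9c9", "T>C": "#a1ce63", "T>G": "#ebc6c4",
}


def plot_spectrum(spectrum: Spectrum96, ax=None, title: str | None = None):
    """Bar plot of a 96-channel spectrum coloured by substitution class."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(14, 3))
    colors = [_CLASS_COLORS[CLASSES[i // 16]] for i in range(96)]
    ax.bar(np.arange(96), spectrum.values, color=colors, width=0.8)
    ax.set_xticks(np.arange(96))
    ax.set_xticklabels([c[0] + c[2] + c[6] for c in CHANNELS], rotation=90, fontsize=5)
    for i, cls in enumerate(CLASSES):
        ax.text(i * 16 + 8, ax.get_ylim()[1], cls, ha="center", va="bottom")
    if title:
        ax.set_title(title)
    return ax


def plot_rainfall(distances, ax=None):
    """Scatter of intermutation distance (log scale) along the genome.

    ``distances`` is the output of
    :func:`clonemut.indels.intermutation_distances`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    xs = np.arange(len(distances))
    ys = [d for _, d in distances]
    ax.scatter(xs, ys, s=4)
    ax.set_yscale("log")
    ax.set_xlabel("mutation index (genome order)")
    ax.set_ylabel("distance to previous SNV (bp)")
    return ax
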