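"""Plotting conveniences (untested rendering helpers).

Quick-look figures for the two headline visualisations: the occupancy
histogram and the pairwise similarity heatmap.  Rendering details are a
convenience, not part of the audited surface.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import NameFrequency, SimilarityMatrix, frequency_histogram

__all__ = ["plot_similarity_heatmap", "plot_frequency_histogram"]


def plot_similarity_heatmap(
    matrix: SimilarityMatrix, path: str | Path, blank_diagonal: bool = True
):
    """Green-to-red heatmap of pairwise SMC values (0–50 scale)."""
    values = matrix.values.astype(float).copy()
    if blank_diagonal:
        np.fill_diagonal(values, np.nan)
    fig, ax = plt.subplots(figsize=(0.4 * len(matrix.labels) + 2,) * 2)
    im = ax.imshow(values, cmap="RdYlGn_r", vmin=0, vmax=50)
    ax.set_xticks(range(len(matrix.labels)), matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="shared trait names (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def plot_frequency_histogram(freq: NameFrequency, path: str | Path):
    """Bar chart of name occupancy (log-scaled counts)."""
    hist = frequency_histogram(freq)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(list(hist.keys()), list(hist.values()), color="#3b7a57")
    ax.set_yscale("log")
    ax.set_xlabel("number of dictionaries containing the name")
    ax.set_ylabel("number of trait names")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
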