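"""Basic diagnostic plots: clustered image map heatmaps and loading plots.

These are intentionally minimal matplotlib renderings of the matrices and
tables the analysis produces; publication-grade figure styling is out of
scope.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402


def plot_cim(matrix: np.ndarray, row_labels: Sequence[str],
             col_labels: Sequence[str], path: str | Path,
             title: str = "Clustered image map") -> None:
    """Heatmap of a (pre-reordered) matrix with diverging colours."""
    fig, ax = plt.subplots(figsize=(max(4, 0.25 * len(col_labels)),
                                    max(4, 0.25 * len(row_labels))))
    vmax = np.nanmax(np.abs(matrix)) or 1.0
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(col_labels)), col_labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(row_labels)), row_labels, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_loadings(table: pd.DataFrame, path: str | Path,
                  title: str = "Component loadings") -> None:
    """Horizontal bar plot of a rank_loadings table (most important on top).

    Bars are coloured by the ``higher_in`` class when present.
    """
    table = table.iloc[::-1]  # most important on top
    colors = None
    if "higher_in" in table.columns:
        classes = list(dict.fromkeys(table["higher_in"]))
        palette = ["#d73027", "#4575b4", "#91bfdb", "#fc8d59"]
        cmap = {c: palette[i % len(palette)] for i, c in enumerate(classes)}
        colors = [cmap[c] for c in table["higher_in"]]
    fig, ax = plt.subplots(figsize=(5, max(2.5, 0.3 * len(table))))
    ax.barh(table["variable"], table["loading"], color=colors)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("loading")
    ax.set_title(title)
    if colors is not None:
        handles = [plt.Rectangle((0, 0), 1, 1, color=cmap[c]) for c in classes]
        ax.legend(handles, classes, fontsize=7, title="higher in")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
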