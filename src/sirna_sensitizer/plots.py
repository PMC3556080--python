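"""Report figures: SI heatmaps and clustered expression heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


def si_heatmap(si_matrix: pd.DataFrame, path=None, title: str = "Sensitization index"):
    """Gene x drug heatmap of SI, rendered on a log2 scale."""
    data = np.log2(si_matrix.to_numpy(dtype=float))
    fig, ax = plt.subplots(
        figsize=(2 + 0.6 * si_matrix.shape[1], 1.5 + 0.25 * si_matrix.shape[0])
    )
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(si_matrix.shape[1]), si_matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(si_matrix.shape[0]), si_matrix.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 SI")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def expression_heatmap(
    matrix: pd.DataFrame,
    path=None,
    cluster_columns: bool = True,
    cluster_rows: bool = False,
    title: str = "Relative expression",
):
    """Row-mean-centered heatmap with average-linkage hierarchical clustering.

    Rows are centered on the per-gene mean so the figure shows relative
    differences between samples; clustering uses Euclidean distance.
    """
    data = matrix.to_numpy(dtype=float)
    data = data - data.mean(axis=1, keepdims=True)
    col_order = np.arange(data.shape[1])
    row_order = np.arange(data.shape[0])
    if cluster_columns and data.shape[1] > 2:
        link = hierarchy.linkage(pdist(data.T), method="average")
        col_order = hierarchy.leaves_list(link)
    if cluster_rows and data.shape[0] > 2:
        link = hierarchy.linkage(pdist(data), method="average")
        row_order = hierarchy.leaves_list(link)
    data = data[np.ix_(row_order, col_order)]
    fig, ax = plt.subplots(
        figsize=(2 + 0.4 * data.shape[1], 1.5 + 0.12 * min(data.shape[0], 80))
    )
    vmax = np.max(np.abs(data)) or 1.0
    im = ax.imshow(data, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(data.shape[1]), matrix.columns[col_order], rotation=45,
                  ha="right", fontsize=6)
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="log2 expression (row-centered)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
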