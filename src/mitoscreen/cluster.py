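"""Hierarchical clustering of correlation matrices (UPGMA, Euclidean).

Signature heat-maps cluster the gene x approach Spearman-correlation
matrix on rows and/or columns with Euclidean distance and average
linkage.  Distances are computed on the raw correlation values (already
bounded in [-1, 1]); no standardization is applied.  Leaf order follows
the plain agglomeration order (no optimal-leaf reordering) unless
requested, so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = ["Dendrogram", "ClusteringResult", "cluster_matrix", "plot_heatmap"]


@dataclass
class Dendrogram:
    """Merge table plus leaf order for one clustered axis.

    ``merges`` is the standard (n-1) x 4 linkage matrix: each row gives
    the two merged node indices (original items are 0..n-1, internal
    nodes n..2n-2 in merge order), the merge height (average pairwise
    Euclidean distance between the two clusters) and the merged size.
    """

    merges: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2] if len(self.merges) else np.empty(0)

    @property
    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        ).astype({"left": int, "right": int, "size": int})


@dataclass
class ClusteringResult:
    rows: Dendrogram | None
    columns: Dendrogram | None
    reordered: pd.DataFrame


def _cluster_axis(values: np.ndarray, labels: list[str], optimal: bool) -> Dendrogram:
    n = values.shape[0]
    if n == 1:
        return Dendrogram(merges=np.empty((0, 4)), leaf_order=[0], labels=labels)
    d = pdist(values, metric="euclidean")
    Z = hierarchy.linkage(d, method="average")
    if optimal:
        Z = hierarchy.optimal_leaf_ordering(Z, d)
    order = hierarchy.leaves_list(Z).tolist()
    return Dendrogram(merges=Z, leaf_order=order, labels=labels)


def cluster_matrix(
    matrix: pd.DataFrame,
    axis: str = "both",
    optimal_order: bool = False,
) -> ClusteringResult:
    """UPGMA-cluster a matrix on rows, columns or both.

    Merge heights under average linkage equal the unweighted mean of all
    cross-cluster pairwise Euclidean distances.  Missing values are a
    structural error (impute or drop first); a single item yields a
    degenerate one-leaf tree.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows|columns|both, got {axis!r}")
    if matrix.shape[0] < 1 or matrix.shape[1] < 1:
        raise ValueError("matrix must be non-empty")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "matrix contains missing values; impute or drop them before clustering"
        )
    rows = cols = None
    if axis in ("rows", "both"):
        rows = _cluster_axis(values, list(map(str, matrix.index)), optimal_order)
    if axis in ("columns", "both"):
        cols = _cluster_axis(values.T, list(map(str, matrix.columns)), optimal_order)
    reordered = matrix
    if rows is not None:
        reordered = reordered.iloc[rows.leaf_order, :]
    if cols is not None:
        reordered = reordered.iloc[:, cols.leaf_order]
    return ClusteringResult(rows=rows, columns=cols, reordered=reordered)


def plot_heatmap(result: ClusteringResult, path, cmap: str = "RdBu_r") -> None:
    """Render the reordered matrix as a raster heat-map (diagnostic view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = result.reordered
    vmax = np.nanmax(np.abs(m.to_numpy())) or 1.0
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * m.shape[1] + 2), max(4, 0.12 * m.shape[0] + 2))
    )
    im = ax.imshow(m.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(m.shape[1]))
    ax.set_xticklabels(m.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(m.shape[0]) if m.shape[0] <= 60 else [])
    if m.shape[0] <= 60:
        ax.set_yticklabels(m.index, fontsize=5)
    fig.colorbar(im, ax=ax, shrink=0.6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
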