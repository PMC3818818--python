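"""Average-linkage (UPGMA) clustering and clustered-image-map export.

Rows (genes) are clustered on Euclidean distance between Z-score
profiles. Pairs with missing entries use pairwise-complete coordinates
rescaled by sqrt(p_total / p_observed) so distances remain comparable;
rows with no comparable coordinates against any other row are excluded
(and reported), mirroring blank rows in the published image maps.

The merge order is fully deterministic: equal distances break toward the
smallest (a, b) cluster-index pair, and the leaf order places the
smaller cluster index on the left.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("nfkbcoupling")


def pairwise_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Euclidean distance with pairwise-complete rescaling; NaN if no overlap."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = ~(np.isnan(x) | np.isnan(y))
    p_obs = int(mask.sum())
    if p_obs == 0:
        return float("nan")
    p_total = x.size
    return float(np.sqrt(np.sum((x[mask] - y[mask]) ** 2) * p_total / p_obs))


@dataclass
class LinkageTree:
    """Average-linkage merge history with deterministic leaf order.

    ``merges`` lists (a, b, height, size) with scipy-style cluster
    indices: leaves are 0..n-1 and merge i creates cluster n+i.
    ``row_labels`` names the clustered rows; ``excluded`` lists rows that
    had no comparable coordinates with any other row.
    """

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    row_labels: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.row_labels)

    def ordered_labels(self) -> list[str]:
        return [self.row_labels[i] for i in self.leaf_order]

    def to_scipy(self) -> np.ndarray:
        """(n-1) x 4 linkage matrix compatible with scipy dendrogram tools."""
        return np.array(
            [[a, b, h, s] for a, b, h, s in self.merges], dtype=float
        )


def cluster_average_linkage(matrix, row_labels=None) -> LinkageTree:
    """UPGMA over the rows of a genes × samples matrix.

    ``matrix`` may be a pandas DataFrame (row labels taken from its
    index) or a 2-D array. At least two mutually comparable rows are
    required. Inter-cluster distance is the unweighted average of all
    cross-pair leaf distances (computed via the exact Lance-Williams
    update), which makes merge heights non-decreasing.
    """
    try:  # pandas duck-typing
        values = matrix.to_numpy(dtype=float)
        labels = list(matrix.index) if row_labels is None else list(row_labels)
    except AttributeError:
        values = np.asarray(matrix, dtype=float)
        labels = (
            [f"row{i}" for i in range(values.shape[0])]
            if row_labels is None else list(row_labels)
        )
    n_all = values.shape[0]
    if n_all < 2:
        raise ValueError("need at least 2 rows to cluster")

    dist_all = np.full((n_all, n_all), np.nan)
    for i in range(n_all):
        for j in range(i + 1, n_all):
            dist_all[i, j] = dist_all[j, i] = pairwise_distance(values[i], values[j])

    comparable = [i for i in range(n_all)
                  if np.any(~np.isnan(np.delete(dist_all[i], i)))]
    excluded = [labels[i] for i in range(n_all) if i not in comparable]
    if excluded:
        logger.warning("WARN cluster rows excluded (no comparable pairs): %s",
                       excluded)
    if len(comparable) < 2:
        raise ValueError("need at least 2 mutually comparable rows")

    keep = np.array(comparable)
    labels_kept = [labels[i] for i in comparable]
    d = dist_all[np.ix_(keep, keep)]
    # remaining NaNs (partial incomparability) merge last
    d = np.where(np.isnan(d), np.inf, d)
    n = len(keep)

    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster index -> size
    dmat: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dmat[(i, j)] = float(d[i, j])

    children: dict[int, tuple[int, int]] = {}
    merges: list[tuple[int, int, float, int]] = []
    next_idx = n
    while len(active) > 1:
        # smallest distance; ties toward the smallest (a, b)
        (a, b), h = min(dmat.items(), key=lambda kv: (kv[1], kv[0]))
        size = active[a] + active[b]
        merges.append((a, b, h, size))
        children[next_idx] = (a, b)
        # Lance-Williams average-linkage update
        for k in list(active):
            if k in (a, b):
                continue
            dak = dmat.pop((min(a, k), max(a, k)))
            dbk = dmat.pop((min(b, k), max(b, k)))
            dmat[(min(k, next_idx), max(k, next_idx))] = (
                active[a] * dak + active[b] * dbk
            ) / size
        del dmat[(a, b)]
        del active[a], active[b]
        active[next_idx] = size
        next_idx += 1

    def leaves(idx: int) -> list[int]:
        if idx < n:
            return [idx]
        a, b = children[idx]
        return leaves(a) + leaves(b)  # smaller cluster index on the left

    order_kept = leaves(next_idx - 1)
    # map back to original row indices
    leaf_order = [int(keep[i]) for i in order_kept]
    return LinkageTree(merges, leaf_order, labels, excluded)


def export_cim(matrix, tree: LinkageTree, table_path, image_path=None) -> None:
    """Write the clustered image map: TSV (rows in leaf order) + raster.

    Missing cells are written as NA and rendered white; the colour scale
    is diverging and symmetric about zero (red high, green low).
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = matrix.data  # ExpressionMatrix
    if sorted(df.index) != sorted(tree.row_labels):
        raise ValueError("tree leaves do not match matrix rows")
    ordered = df.loc[tree.ordered_labels()]
    flat = ordered.copy()
    if isinstance(flat.columns, pd.MultiIndex):
        flat.columns = [f"{c}:{t:g}" for c, t in flat.columns]
    flat.index.name = "gene"
    flat.to_csv(table_path, sep="\t", na_rep="NA")

    if image_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        vals = np.ma.masked_invalid(ordered.to_numpy(float))
        vmax = float(np.abs(vals).max()) or 1.0
        cmap = plt.get_cmap("RdYlGn_r").copy()
        cmap.set_bad("white")
        fig, ax = plt.subplots(
            figsize=(max(4, 0.35 * vals.shape[1]), max(4, 0.16 * vals.shape[0]))
        )
        im = ax.imshow(vals, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
        ax.set_yticks(range(len(ordered.index)))
        ax.set_yticklabels(ordered.index, fontsize=5)
        ax.set_xticks(range(len(flat.columns)))
        ax.set_xticklabels(flat.columns, rotation=90, fontsize=6)
        fig.colorbar(im, ax=ax, label="Z-score (SD units)")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
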