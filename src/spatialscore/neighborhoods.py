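"""Cellular neighborhoods (CNs) from k-NN window composition vectors.

Each cell is described by the cell-type composition of its *window*: itself
plus its ``w - 1`` nearest neighbours within the same tissue-microarray spot
(Euclidean distance on the segmentation centroids). Windows are clustered
with k-means; a cell's CN is the cluster of the window centred on it. CN
frequencies per spot are the downstream group-comparison currency.

Windows never cross spot boundaries — cores are physically separate pieces
of tissue. Spots smaller than the window simply use every cell they have.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans, MiniBatchKMeans

from .io import CellTable


@dataclass
class NeighborhoodModel:
    """Fitted CN model: window size, centroids, and per-cell assignments."""

    window_size: int
    n_neighborhoods: int
    centroids: pd.DataFrame  # k x n_types, rows sum to 1
    assignments: pd.Series  # cell_id -> CN label in 1..k
    enrichment: pd.DataFrame  # k x n_types mean window composition
    seed: int


def window_compositions(cells: CellTable, w: int) -> pd.DataFrame:
    """Per-cell cell-type frequency vector over the w-cell window.

    Returns a DataFrame indexed by cell_id (input row order) with one column
    per vocabulary type; every row sums to 1. The centre cell counts toward
    its own window. Nearest-neighbour ties are broken by lowest row index.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    types = list(cells.cell_types)
    type_idx = {t: i for i, t in enumerate(types)}
    df = cells.df
    codes = df["cell_type"].map(type_idx).to_numpy()
    out = np.zeros((len(df), len(types)))

    for _spot, sub in df.groupby("spot_id", sort=False):
        rows = sub.index.to_numpy()
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        k = min(w, len(rows))
        tree = cKDTree(xy)
        _, nbr = tree.query(xy, k=k)
        nbr = np.asarray(nbr).reshape(len(rows), k)
        window_codes = codes[rows[nbr]]
        for ci in range(len(types)):
            out[rows, ci] = (window_codes == ci).mean(axis=1)

    return pd.DataFrame(out, index=pd.Index(df["cell_id"], name="cell_id"), columns=types)


def cluster_neighborhoods(
    vectors: pd.DataFrame,
    k: int,
    seed: int,
    w: int | None = None,
    mini_batch: bool = False,
) -> NeighborhoodModel:
    """k-means over window composition vectors (k-means++ init, n_init=10).

    ``mini_batch=True`` switches to MiniBatchKMeans for very large tables;
    the full-batch default is deterministic given the seed.
    """
    X = vectors.to_numpy(dtype=float)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct window vectors")
    cls = MiniBatchKMeans if mini_batch else KMeans
    km = cls(n_clusters=k, n_init=10, random_state=seed).fit(X)
    labels = km.labels_ + 1  # CN labels are 1..k

    centroids = km.cluster_centers_.clip(min=0.0)
    centroids = centroids / centroids.sum(axis=1, keepdims=True)
    enrich = np.vstack([X[labels == c].mean(axis=0) for c in range(1, k + 1)])
    idx = pd.Index(range(1, k + 1), name="cn")
    return NeighborhoodModel(
        window_size=w if w is not None else 0,
        n_neighborhoods=k,
        centroids=pd.DataFrame(centroids, index=idx, columns=vectors.columns),
        assignments=pd.Series(labels, index=vectors.index, name="cn"),
        enrichment=pd.DataFrame(enrich, index=idx, columns=vectors.columns),
        seed=seed,
    )


def detect_neighborhoods(
    cells: CellTable, w: int = 10, k: int = 10, seed: int = 0, mini_batch: bool = False
) -> NeighborhoodModel:
    """Convenience: window vectors + clustering in one call (defaults w=10, k=10)."""
    vectors = window_compositions(cells, w)
    model = cluster_neighborhoods(vectors, k, seed, w=w, mini_batch=mini_batch)
    return model


def cn_frequencies(model: NeighborhoodModel, cells: CellTable) -> pd.DataFrame:
    """Per-spot CN proportion table (spots x k); rows sum to 1."""
    df = cells.df
    labels = model.assignments.reindex(df["cell_id"])
    if labels.isna().any():
        raise ValueError("assignments do not cover all cells")
    tab = pd.crosstab(df["spot_id"].to_numpy(), labels.to_numpy())
    tab = tab.reindex(columns=range(1, model.n_neighborhoods + 1), fill_value=0)
    freq = tab.div(tab.sum(axis=1), axis=0)
    freq.index.name = "spot_id"
    freq.columns = pd.Index(range(1, model.n_neighborhoods + 1), name="cn")
    return freq


def voronoi_plot(cells: CellTable, model: NeighborhoodModel, spot_id: str, path):
    """Optional CN-coloured Voronoi diagram for one spot (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.spatial import Voronoi, voronoi_plot_2d

    sub = cells.spot(spot_id)
    xy = sub[["x", "y"]].to_numpy(dtype=float)
    labels = model.assignments.reindex(sub["cell_id"]).to_numpy()
    vor = Voronoi(xy)
    fig, ax = plt.subplots(figsize=(6, 6))
    voronoi_plot_2d(vor, ax=ax, show_points=False, show_vertices=False, line_width=0.3)
    cmap = plt.get_cmap("tab10")
    ax.scatter(xy[:, 0], xy[:, 1], c=[cmap((l - 1) % 10) for l in labels], s=4)
    ax.set_title(f"CNs in spot {spot_id}")
    ax.set_aspect("equal")
    fig.savefig(path, dpi=150)
    plt.close(fig)
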