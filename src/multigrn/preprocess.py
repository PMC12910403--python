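"""QC, normalization, dimensionality reduction and clustering.

The RNA modality is depth-normalized and log-transformed; the ATAC modality
is TF-IDF normalized (the log1p(tf * idf * scale) variant common in scATAC
toolkits) and embedded with LSI (truncated SVD).  Components whose absolute
Pearson correlation with per-cell total counts exceeds a threshold are
flagged as depth-driven and dropped from downstream use.  Cells are
clustered with Leiden community detection on a shared-nearest-neighbor
graph, seeded for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds
from sklearn.neighbors import NearestNeighbors

from .exceptions import AlignmentError, ConfigurationError, EmptyResultError
from .io import CountMatrix


@dataclass
class Embedding:
    """A cells x k coordinate matrix with depth-confounded components flagged."""

    cell_ids: list[str]
    coordinates: np.ndarray
    method: str  # "PCA" | "LSI"
    components_dropped: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise AlignmentError("embedding rows do not match cell ids")
        if self.coordinates.shape[1] < 2:
            raise ConfigurationError("embedding needs k >= 2 components")

    @property
    def usable(self) -> np.ndarray:
        """Coordinates with flagged components excluded."""
        keep = [j for j in range(self.coordinates.shape[1]) if j not in self.components_dropped]
        return self.coordinates[:, keep]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_cells(
    matrix: CountMatrix, cells: pd.DataFrame, min_counts: float = 0, min_features: int = 0
) -> tuple[CountMatrix, pd.DataFrame]:
    """Drop cells below either total-count or detected-feature threshold."""
    if min_counts < 0 or min_features < 0:
        raise ConfigurationError("min_counts and min_features must be >= 0")
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    nfeat = matrix.values.getnnz(axis=1)
    keep = (totals >= min_counts) & (nfeat >= min_features)
    if not keep.any():
        raise EmptyResultError("all cells removed by filter_cells")
    out_cells = cells.loc[np.asarray(keep)].reset_index(drop=True)
    return matrix.subset_cells(keep), out_cells


def subset_neurons(matrix: CountMatrix, cells: pd.DataFrame) -> tuple[CountMatrix, pd.DataFrame]:
    """Restrict both matrix and table to cells labeled \"Neurons\"."""
    if list(cells["cell_id"]) != matrix.cell_ids:
        raise AlignmentError("cell table does not align with matrix cells")
    keep = (cells["cell_class"] == "Neurons").to_numpy()
    if not keep.any():
        raise EmptyResultError("no cells labeled 'Neurons'")
    return matrix.subset_cells(keep), cells.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def lognormalize_rna(matrix: CountMatrix, scale_factor: float = 1e4) -> CountMatrix:
    """value = log1p(count / cell_total * scale_factor); zeros stay zero."""
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise EmptyResultError(
            f"cells with zero total counts: {[matrix.cell_ids[i] for i in zero[:10]]}"
        )
    x = matrix.values.tocsr(copy=True).astype(float)
    scale = scale_factor / totals
    x.data *= np.repeat(scale, np.diff(x.indptr))
    x.data = np.log1p(x.data)
    return CountMatrix(x, matrix.cell_ids, matrix.feature_ids, matrix.modality, normalized=True)


def tfidf_normalize_atac(matrix: CountMatrix, scale_factor: float = 1e4) -> CountMatrix:
    """TF-IDF: value = log1p(count/cell_total * n_cells/n_cells_with_feature * scale).

    Features observed in zero cells have no nonzero entries and therefore
    stay identically zero; the zero pattern is preserved everywhere.
    """
    totals = np.asarray(matrix.values.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise EmptyResultError(
            f"cells with zero total counts: {[matrix.cell_ids[i] for i in zero[:10]]}"
        )
    x = matrix.values.tocsr(copy=True).astype(float)
    x.data *= np.repeat(1.0 / totals, np.diff(x.indptr))  # term frequency
    df = matrix.values.getnnz(axis=0).astype(float)
    idf = np.divide(matrix.n_cells, df, out=np.zeros_like(df), where=df > 0)
    x = x.tocsc()
    x.data *= np.repeat(idf, np.diff(x.indptr))
    x.data = np.log1p(x.data * scale_factor)
    return CountMatrix(
        x.tocsr(), matrix.cell_ids, matrix.feature_ids, matrix.modality, normalized=True
    )


# ---------------------------------------------------------------------------
# dimensionality reduction
# ---------------------------------------------------------------------------

def _flag_depth_components(
    coords: np.ndarray, total_counts: np.ndarray, max_abs_corr: float
) -> list[int]:
    t = total_counts - total_counts.mean()
    tn = np.linalg.norm(t)
    dropped = []
    for j in range(coords.shape[1]):
        c = coords[:, j] - coords[:, j].mean()
        cn = np.linalg.norm(c)
        if cn == 0 or tn == 0:
            continue
        if abs(float(c @ t) / (cn * tn)) > max_abs_corr:
            dropped.append(j)
    return dropped


def run_lsi(
    matrix: CountMatrix,
    n_components: int = 30,
    total_counts: np.ndarray | None = None,
    depth_corr_threshold: float = 0.9,
) -> Embedding:
    """Latent semantic indexing: truncated SVD of the TF-IDF matrix.

    Components correlating with sequencing depth (|r| > threshold against
    per-cell total counts) are flagged in ``components_dropped``.
    """
    if n_components >= min(matrix.values.shape):
        raise ConfigurationError(
            f"n_components {n_components} must be < min(matrix dims) {min(matrix.values.shape)}"
        )
    u, s, vt = svds(sp.csr_matrix(matrix.values, dtype=float), k=n_components, random_state=0)
    order = np.argsort(s)[::-1]
    u, s = u[:, order], s[order]
    # deterministic sign: make the largest-|u| entry of each component positive
    for j in range(u.shape[1]):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    coords = u * s
    if total_counts is None:
        total_counts = np.asarray(matrix.values.sum(axis=1)).ravel()
    dropped = _flag_depth_components(coords, np.asarray(total_counts, float), depth_corr_threshold)
    return Embedding(matrix.cell_ids, coords, "LSI", dropped)


def run_pca(
    matrix: CountMatrix,
    n_components: int = 30,
    scale: bool = True,
    total_counts: np.ndarray | None = None,
    depth_corr_threshold: float = 0.9,
) -> Embedding:
    """PCA on centered (and, by default, unit-variance) values."""
    if n_components >= min(matrix.values.shape):
        raise ConfigurationError(
            f"n_components {n_components} must be < min(matrix dims) {min(matrix.values.shape)}"
        )
    x = matrix.dense().astype(float)
    x -= x.mean(axis=0)
    if scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
    u, s, vt = svds(x, k=n_components, random_state=0)
    order = np.argsort(s)[::-1]
    u, s = u[:, order], s[order]
    for j in range(u.shape[1]):
        i = np.argmax(np.abs(u[:, j]))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
    coords = u * s
    if total_counts is None:
        total_counts = np.asarray(matrix.values.sum(axis=1)).ravel()
    dropped = _flag_depth_components(coords, np.asarray(total_counts, float), depth_corr_threshold)
    return Embedding(matrix.cell_ids, coords, "PCA", dropped)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _snn_graph(coords: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbor graph: kNN edges weighted by neighborhood
    Jaccard overlap, weak edges (< 1/15) pruned."""
    n = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(coords)
    knn = nn.kneighbors_graph(coords, mode="connectivity")  # includes self
    shared = (knn @ knn.T).tocoo()  # |N_i & N_j|
    rows, cols, inter = shared.row, shared.col, shared.data
    keep = rows < cols
    rows, cols, inter = rows[keep], cols[keep], inter[keep]
    jacc = inter / (2 * n_neighbors - inter)
    strong = jacc >= 1.0 / 15.0
    g = ig.Graph(n=n, edges=list(zip(rows[strong].tolist(), cols[strong].tolist())))
    g.es["weight"] = jacc[strong].tolist()
    return g


def cluster_cells(
    embedding: Embedding,
    resolution: float = 0.5,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on an SNN graph of the embedding.

    Returns integer labels 0..C-1, relabeled by decreasing cluster size;
    deterministic given the seed.
    """
    coords = embedding.usable
    n = coords.shape[0]
    if n < n_neighbors:
        raise ConfigurationError(f"need at least n_neighbors={n_neighbors} cells, got {n}")
    g = _snn_graph(coords, n_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # stable relabel by size, ties by first occurrence
    ids, counts = np.unique(labels, return_counts=True)
    first = np.array([np.argmax(labels == i) for i in ids])
    order = np.lexsort((first, -counts))
    remap = {int(ids[k]): r for r, k in enumerate(order)}
    return np.asarray([remap[int(l)] for l in labels])
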