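"""Cross-modality TF-gene regulatory network inference.

For every candidate TF (differentially expressed in neurons) and every gene
with a detectable TSS window, the Spearman rank correlation between the
TF's per-cell expression and the gene's per-cell TSS accessibility is
computed across neurons; pairs with |rho| > 0.3 and p < 0.05 (raw,
unadjusted — the stated retention rule) become directed TF -> target edges.
The focal TF's top-k targets by |rho| form the reported subnetwork.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .diff import bh_adjust
from .exceptions import AlignmentError, ConfigurationError, EmptyResultError
from .io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryEdge:
    tf: str
    target: str
    rho: float
    p: float
    n_cells: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ConfigurationError(f"|rho| > 1 for edge {self.tf}->{self.target}")


@dataclass
class RegulatoryNetwork:
    edges: list[RegulatoryEdge]
    tf_nodes: list[str]
    target_nodes: list[str]
    r_min: float
    alpha: float

    def __post_init__(self) -> None:
        for e in self.edges:
            if not (abs(e.rho) > self.r_min and e.p < self.alpha):
                raise ConfigurationError(
                    f"edge {e.tf}->{e.target} violates |rho|>{self.r_min}, p<{self.alpha}"
                )

    @property
    def n_edges(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (Pearson of average ranks) and two-sided p from the
    t approximation with n-2 df; |rho| = 1 gives p = 0; constant input
    gives (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise AlignmentError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ConfigurationError(f"spearman needs n >= 3, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ConfigurationError("spearman requires finite values")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    return rho, _rho_pvalue(np.array([rho]), x.size)[0]


def _rho_pvalue(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from t = rho * sqrt((n-2) / (1-rho^2)), df = n-2."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))


def _rank_standardize(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-rank then z-score; returns (standardized ranks, constant mask)."""
    ranks = scipy.stats.rankdata(mat, axis=0)
    mu = ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    const = sd == 0
    sd = np.where(const, 1.0, sd)
    return (ranks - mu) / sd, const


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_tf_gene_network(
    tfs: Sequence[str],
    genes: Sequence[str],
    rna_norm: CountMatrix,
    atac_tss_norm: CountMatrix,
    r_min: float = 0.3,
    alpha: float = 0.05,
    min_cells_nonzero: int = 3,
    adjust: bool = False,
    allow_self_loops: bool = False,
) -> RegulatoryNetwork:
    """Spearman TF-expression vs gene-TSS-accessibility network.

    Both matrices must carry the same cells in the same order (neurons of
    the analyzed timepoint).  Genes with fewer than ``min_cells_nonzero``
    nonzero TSS cells are excluded; constant (NA-rho) pairs are dropped with
    a logged count.  ``adjust=True`` applies BH across all candidate pairs
    before the alpha cut (a deviation from the raw-p retention rule, logged).
    """
    if rna_norm.cell_ids != atac_tss_norm.cell_ids:
        raise AlignmentError("RNA and ATAC_TSS matrices carry different cell sets/orders")
    n = rna_norm.n_cells
    if n < 3:
        raise ConfigurationError("need at least 3 cells")
    tfs = list(tfs)
    if not tfs:
        return RegulatoryNetwork([], [], [], r_min, alpha)

    tss_dense = atac_tss_norm.subset_features(list(genes)).dense().astype(float)
    detect = (tss_dense > 0).sum(axis=0) >= min_cells_nonzero
    genes_kept = [g for g, d in zip(genes, detect) if d]
    if not genes_kept:
        return RegulatoryNetwork([], tfs, [], r_min, alpha)
    tss_dense = tss_dense[:, detect]

    tf_dense = rna_norm.subset_features(tfs).dense().astype(float)
    zx, const_x = _rank_standardize(tf_dense)
    zy, const_y = _rank_standardize(tss_dense)
    rho = (zx.T @ zy) / n  # Pearson of ranks
    rho = np.clip(rho, -1.0, 1.0)
    rho[const_x, :] = np.nan
    rho[:, const_y] = np.nan
    pmat = _rho_pvalue(rho, n)

    n_na = int(np.isnan(rho).sum())
    if n_na:
        logger.info("build_tf_gene_network: dropped %d constant (NA-rho) pairs", n_na)

    if adjust:
        logger.warning(
            "build_tf_gene_network: BH adjustment across pairs enabled — "
            "deviates from the raw-p retention rule"
        )
        flat = pmat.ravel()
        ok = ~np.isnan(flat)
        adj = flat.copy()
        adj[ok] = bh_adjust(flat[ok])
        pmat = adj.reshape(pmat.shape)

    edges = []
    for i, tf in enumerate(tfs):
        for j, g in enumerate(genes_kept):
            if tf == g and not allow_self_loops:
                continue
            r, p = rho[i, j], pmat[i, j]
            if np.isnan(r):
                continue
            if abs(r) > r_min and p < alpha:
                edges.append(RegulatoryEdge(tf, g, float(r), float(p), n))
    targets = sorted({e.target for e in edges})
    return RegulatoryNetwork(edges, tfs, targets, r_min, alpha)


def focal_tf_subnetwork(network: RegulatoryNetwork, focal_tf: str, k: int = 20) -> RegulatoryNetwork:
    """The focal TF's top-k targets by |rho| (ties: ascending p, then id)."""
    if focal_tf not in network.tf_nodes:
        raise EmptyResultError(f"focal TF {focal_tf!r} is not a TF node of the network")
    mine = [e for e in network.edges if e.tf == focal_tf]
    mine.sort(key=lambda e: (-abs(e.rho), e.p, e.target))
    top = mine[:k]
    return RegulatoryNetwork(
        top, [focal_tf], sorted({e.target for e in top}), network.r_min, network.alpha
    )


def export_network_plot_data(network: RegulatoryNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for visualization, deterministically ordered."""
    tf_set = {e.tf for e in network.edges}
    nodes = [(t, "TF") for t in sorted(tf_set)]
    nodes += [(g, "target") for g in sorted({e.target for e in network.edges} - tf_set)]
    nodes_df = pd.DataFrame(nodes, columns=["node", "role"])
    edges_sorted = sorted(network.edges, key=lambda e: (e.tf, e.target))
    edges_df = pd.DataFrame(
        [
            (e.tf, e.target, e.rho, abs(e.rho), "positive" if e.rho >= 0 else "negative", e.p)
            for e in edges_sorted
        ],
        columns=["tf", "target", "rho", "magnitude", "sign", "p"],
    )
    return nodes_df, edges_df
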