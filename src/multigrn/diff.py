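"""Differential accessibility / expression between an injury timepoint and
the uninjured control.

The test is the Wilcoxon rank-sum (Mann-Whitney U) on normalized values,
with Benjamini-Hochberg adjustment across all *tested* features.  Features
detected in too few cells of both groups (the accessibility/expression
fraction filter, > 20% by default) are excluded *before* testing, so the BH
denominator is the post-filter feature count — the order filter -> test ->
adjust is fixed and regression-tested.  Peaks lacking GC metadata are
excluded from downstream motif work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import AlignmentError, ConfigurationError, EmptyResultError
from .io import CountMatrix, Peak

logger = logging.getLogger(__name__)


@dataclass
class DifferentialFeatureResult:
    feature_id: str
    log2_fc: float
    pct_group1: float
    pct_group2: float
    p: float
    p_adj: float
    direction: str  # "up" | "down"

    def __post_init__(self) -> None:
        for name in ("pct_group1", "pct_group2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name}={v} outside [0, 1]")


def results_to_frame(results: Sequence[DifferentialFeatureResult]) -> pd.DataFrame:
    cols = ["feature_id", "log2_fc", "pct_group1", "pct_group2", "p", "p_adj", "direction"]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in results], columns=cols)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _asymptotic_u_p(u1: np.ndarray, n1: int, n2: int, tie_term: np.ndarray) -> np.ndarray:
    """Two-sided normal approximation with tie and continuity correction."""
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    diff = u1 - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    p = np.where(var == 0, 1.0, p)
    return np.minimum(p, 1.0)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for group x) and two-sided p.

    Exact p by enumeration of the permutation distribution when
    n1 + n2 <= 12 and there are no ties; otherwise the normal approximation
    with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyResultError("wilcoxon_rank_sum: both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= 12 and not has_ties:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = scipy.stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    u1 = r1 - x.size * (x.size + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    p = _asymptotic_u_p(np.array([u1]), x.size, y.size, np.array([tie_term]))[0]
    return float(u1), float(p)


def _wilcoxon_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Column-wise two-sided Wilcoxon p for group matrices x (n1 x m), y (n2 x m).

    Uses the same asymptotic formula as the scalar test (single-cell group
    sizes are far beyond the exact-enumeration regime)."""
    n1, m = x.shape
    n2 = y.shape[0]
    pooled = np.vstack([x, y])
    ranks = scipy.stats.rankdata(pooled, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    tie_term = np.empty(m)
    ps = np.sort(pooled, axis=0)
    for j in range(m):  # run-length encode each sorted column
        col = ps[:, j]
        change = np.flatnonzero(col[1:] != col[:-1])
        counts = np.diff(np.concatenate([[-1], change, [col.size - 1]])).astype(float)
        tie_term[j] = (counts**3 - counts).sum()
    return _asymptotic_u_p(u1, n1, n2, tie_term)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential features
# ---------------------------------------------------------------------------

def find_differential_features(
    matrix: CountMatrix,
    cells: pd.DataFrame,
    condition: str,
    control: str = "uninjured",
    min_pct: float = 0.20,
    alpha_adj: float = 0.05,
    return_all: bool = False,
) -> list[DifferentialFeatureResult]:
    """Wilcoxon differential test of ``condition`` vs ``control``.

    Features where neither group exceeds ``min_pct`` nonzero cells are
    excluded before testing; BH runs across the tested features; only
    features with adjusted p < ``alpha_adj`` are returned (all tested
    features with ``return_all=True``).  log2 fold change is computed on
    expm1-ed group means with pseudocount 1.
    """
    if list(cells["cell_id"]) != matrix.cell_ids:
        raise AlignmentError("cell table does not align with matrix cells")
    cond_vec = cells["condition"].astype(str).to_numpy()
    for label in (condition, control):
        if not (cond_vec == label).any():
            raise EmptyResultError(f"no cells with condition {label!r}")
    g1 = np.flatnonzero(cond_vec == condition)
    g2 = np.flatnonzero(cond_vec == control)

    dense = matrix.dense().astype(float)
    x, y = dense[g1], dense[g2]
    pct1 = (x > 0).mean(axis=0)
    pct2 = (y > 0).mean(axis=0)
    tested = np.flatnonzero(np.maximum(pct1, pct2) > min_pct)
    if tested.size == 0:
        return []

    pvals = _wilcoxon_matrix(x[:, tested], y[:, tested])
    padj = bh_adjust(pvals)
    m1 = np.expm1(x[:, tested]).mean(axis=0)
    m2 = np.expm1(y[:, tested]).mean(axis=0)
    lfc = np.log2((m1 + 1.0) / (m2 + 1.0))

    out = []
    for k, j in enumerate(tested):
        if not return_all and not (padj[k] < alpha_adj):
            continue
        out.append(
            DifferentialFeatureResult(
                feature_id=matrix.feature_ids[j],
                log2_fc=float(lfc[k]),
                pct_group1=float(pct1[j]),
                pct_group2=float(pct2[j]),
                p=float(pvals[k]),
                p_adj=float(padj[k]),
                direction="up" if lfc[k] > 0 else "down",
            )
        )
    return out


def exclude_missing_gc(
    dap_list: Sequence[DifferentialFeatureResult], peaks: Mapping[str, Peak] | Iterable[Peak]
) -> list[DifferentialFeatureResult]:
    """Drop DAPs whose peak has missing GC metadata (logged count)."""
    if not isinstance(peaks, Mapping):
        peaks = {p.peak_id: p for p in peaks}
    kept = []
    removed = 0
    for r in dap_list:
        peak = peaks.get(r.feature_id)
        gc = None if peak is None else peak.gc_fraction
        if gc is None or (isinstance(gc, float) and np.isnan(gc)):
            removed += 1
        else:
            kept.append(r)
    logger.info("exclude_missing_gc: removed %d of %d DAPs", removed, len(dap_list))
    return kept


def find_differential_tfs(
    rna_matrix: CountMatrix,
    cells: pd.DataFrame,
    tf_name_set: Iterable[str],
    condition: str,
    control: str = "uninjured",
    min_pct: float = 0.20,
    alpha_adj: float = 0.05,
) -> list[DifferentialFeatureResult]:
    """Differential test restricted to TF genes (BH within the TF set).

    TF names are matched to gene ids case-insensitively."""
    tf_name_set = list(tf_name_set)
    if not tf_name_set:
        raise ConfigurationError("tf_name_set must be non-empty")
    by_lower = {}
    for g in rna_matrix.feature_ids:
        by_lower.setdefault(g.lower(), g)
    tf_genes = sorted({by_lower[t.lower()] for t in tf_name_set if t.lower() in by_lower})
    if not tf_genes:
        raise EmptyResultError("tf_name_set shares no genes with the RNA matrix")
    sub = rna_matrix.subset_features(tf_genes)
    return find_differential_features(
        sub, cells, condition, control=control, min_pct=min_pct, alpha_adj=alpha_adj
    )
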