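"""Motif occurrence annotation in peaks and GC-matched enrichment testing.

PFMs are converted to log2-odds position weight matrices with a small
pseudocount split by background frequency; peaks are scanned on both strands
and a peak counts as motif-positive if any window on either strand reaches
the bit-score threshold (a fraction of the motif's maximum score by
default).  Over-representation of a motif among query peaks (the DAPs) is
tested with the one-sided hypergeometric upper tail against a background
peak population, optionally GC-matched by quantile-bin sampling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .exceptions import ConfigurationError, EmptyResultError
from .io import Peak, PositionFrequencyMatrix

logger = logging.getLogger(__name__)

UNIFORM_BG = np.full(4, 0.25)
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length over {A,C,G,T,N}; N counts in the denominator only."""
    seq = sequence.upper()
    if not seq:
        raise ConfigurationError("gc_fraction: empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ConfigurationError(f"gc_fraction: non-ACGTN characters {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# PWM construction and scanning
# ---------------------------------------------------------------------------

def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background_freqs: np.ndarray = UNIFORM_BG,
    pseudocount: float = 0.8,
) -> np.ndarray:
    """log2((count + pc*bg) / (colsum + pc) / bg) per cell -> 4 x L bit scores."""
    bg = np.asarray(background_freqs, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or (bg <= 0).any():
        raise ConfigurationError("background_freqs must be 4 positive values summing to 1")
    counts = pfm.counts
    probs = (counts + pseudocount * bg[:, None]) / (counts.sum(axis=0) + pseudocount)
    return np.log2(probs / bg[:, None])


def max_pwm_score(pwm: np.ndarray) -> float:
    return float(pwm.max(axis=0).sum())


def _encode(sequence: str) -> np.ndarray:
    return np.asarray([_BASE_INDEX[b] for b in sequence.upper()], dtype=np.int8)


def _window_scores(codes: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every window; N bases contribute 0 bits (background-neutral)."""
    L = pwm.shape[1]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0)
    pwm_n = np.vstack([pwm, np.zeros((1, L))])  # row 4 = N
    idx = np.arange(L)[None, :] + np.arange(n_win)[:, None]
    return pwm_n[codes[idx], np.arange(L)[None, :]].sum(axis=1)


def scan_motif(
    sequence: str,
    pfm: PositionFrequencyMatrix,
    background_freqs: np.ndarray = UNIFORM_BG,
    threshold_bits: float | None = None,
    threshold_frac: float = 0.8,
) -> list[tuple[int, str, float]]:
    """Hit positions of a motif on both strands of a sequence.

    Returns (start, strand, bits) triples in forward coordinates; sequences
    shorter than the motif yield an empty list.  The default threshold is
    ``threshold_frac`` of the motif's maximum achievable score.
    """
    pwm = pfm_to_pwm(pfm, background_freqs)
    if threshold_bits is None:
        threshold_bits = threshold_frac * max_pwm_score(pwm)
    codes = _encode(sequence)
    L = pfm.length
    hits: list[tuple[int, str, float]] = []
    fwd = _window_scores(codes, pwm)
    # reverse strand: scan the reverse-complement PWM on the forward sequence
    rc_pwm = pwm[::-1, ::-1]
    rev = _window_scores(codes, rc_pwm)
    for pos in np.flatnonzero(fwd >= threshold_bits):
        hits.append((int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(rev >= threshold_bits):
        hits.append((int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass
class MotifOccurrenceMatrix:
    """Binary peak x motif indicators at a fixed scan threshold."""

    peak_ids: list[str]
    motif_ids: list[str]
    indicators: np.ndarray  # bool, peaks x motifs
    scan_threshold_bits: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.indicators = np.asarray(self.indicators, dtype=bool)
        if self.indicators.shape != (len(self.peak_ids), len(self.motif_ids)):
            raise ConfigurationError("occurrence matrix dimensions do not match ids")

    def positives(self, motif_id: str, peak_ids: Sequence[str]) -> int:
        j = self.motif_ids.index(motif_id)
        row = {p: i for i, p in enumerate(self.peak_ids)}
        return int(sum(self.indicators[row[p], j] for p in peak_ids))


def scan_peaks(
    peaks: Sequence[Peak],
    pfms: Sequence[PositionFrequencyMatrix],
    background_freqs: np.ndarray = UNIFORM_BG,
    threshold_frac: float = 0.8,
) -> MotifOccurrenceMatrix:
    """Annotate every peak with every motif (any-strand hit at threshold)."""
    ind = np.zeros((len(peaks), len(pfms)), dtype=bool)
    thresholds = {}
    for j, pfm in enumerate(pfms):
        pwm = pfm_to_pwm(pfm, background_freqs)
        thr = threshold_frac * max_pwm_score(pwm)
        thresholds[pfm.motif_id] = thr
        rc_pwm = pwm[::-1, ::-1]
        for i, peak in enumerate(peaks):
            if peak.sequence is None or len(peak.sequence) < pfm.length:
                continue
            codes = _encode(peak.sequence)
            if (_window_scores(codes, pwm) >= thr).any() or (
                _window_scores(codes, rc_pwm) >= thr
            ).any():
                ind[i, j] = True
    return MotifOccurrenceMatrix(
        [p.peak_id for p in peaks], [m.motif_id for m in pfms], ind, thresholds
    )


# ---------------------------------------------------------------------------
# GC-matched background
# ---------------------------------------------------------------------------

def match_background_by_gc(
    query_peaks: Sequence[Peak],
    pool_peaks: Sequence[Peak],
    n_background: int,
    n_bins: int = 10,
    seed: int = 0,
) -> list[Peak]:
    """Sample a background whose GC histogram matches the query's.

    GC is binned into ``n_bins`` quantile bins of the query distribution;
    the background is drawn without replacement so bin proportions match the
    query's within rounding.
    """
    q_ids = {p.peak_id for p in query_peaks}
    if any(p.peak_id in q_ids for p in pool_peaks):
        raise ConfigurationError("background pool must be disjoint from the query set")
    if len(pool_peaks) < n_background:
        raise ConfigurationError(
            f"pool has {len(pool_peaks)} peaks but n_background={n_background}"
        )
    qgc = np.array([_require_gc(p) for p in query_peaks])
    pgc = np.array([_require_gc(p) for p in pool_peaks])
    q_bins, p_bins, eligible, edges, n_eff = _gc_bins(qgc, pgc, n_bins)
    take = _apportion(q_bins, n_eff, n_background)

    rng = np.random.default_rng(seed)
    chosen: list[Peak] = []
    for b in range(n_eff):
        if take[b] == 0:
            continue
        avail = np.flatnonzero((p_bins == b) & eligible)
        if avail.size < take[b]:
            raise ConfigurationError(
                f"GC bin {b} ([{edges[b]:.3f}, {edges[min(b + 1, len(edges) - 1)]:.3f}]) "
                f"needs {take[b]} background peaks but the pool has {avail.size}"
            )
        for i in rng.choice(avail, size=take[b], replace=False):
            chosen.append(pool_peaks[int(i)])
    return chosen


def _gc_bins(qgc: np.ndarray, pgc: np.ndarray, n_bins: int):
    """Quantile bins of the query GC; pool peaks outside the query range
    (with a small tolerance) are marked ineligible."""
    edges = np.unique(np.quantile(qgc, np.linspace(0, 1, n_bins + 1)))
    inner = edges[1:-1]
    q_bins = np.searchsorted(inner, qgc, side="right")
    p_bins = np.searchsorted(inner, pgc, side="right")
    n_eff = max(len(edges) - 1, 1)
    span = qgc.max() - qgc.min()
    tol = span / (2 * n_bins) if span > 0 else 1e-9
    eligible = (pgc >= qgc.min() - tol) & (pgc <= qgc.max() + tol)
    return q_bins, p_bins, eligible, edges, n_eff


def _apportion(q_bins: np.ndarray, n_eff: int, n_background: int) -> np.ndarray:
    """Largest-remainder apportionment of the background over query bins."""
    prop = np.bincount(q_bins, minlength=n_eff) / q_bins.size
    raw = prop * n_background
    take = np.floor(raw).astype(int)
    rem = n_background - take.sum()
    order = np.argsort(-(raw - take))
    take[order[:rem]] += 1
    return take


def feasible_background_size(
    query_peaks: Sequence[Peak],
    pool_peaks: Sequence[Peak],
    n_requested: int,
    n_bins: int = 10,
) -> int:
    """Largest background size <= ``n_requested`` for which every query GC
    bin can be filled from the pool without replacement."""
    qgc = np.array([_require_gc(p) for p in query_peaks])
    pgc = np.array([_require_gc(p) for p in pool_peaks])
    q_bins, p_bins, eligible, _, n_eff = _gc_bins(qgc, pgc, n_bins)
    avail = np.bincount(p_bins[eligible], minlength=n_eff)
    n = min(n_requested, int(eligible.sum()))
    while n > 0:
        if (_apportion(q_bins, n_eff, n) <= avail).all():
            return n
        n -= 1
    return 0


def _require_gc(p: Peak) -> float:
    if p.gc_fraction is None or np.isnan(p.gc_fraction):
        raise ConfigurationError(f"peak {p.peak_id} has missing gc_fraction")
    return p.gc_fraction


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class MotifEnrichmentRecord:
    motif_id: str
    motif_name: str
    n_query_pos: int
    n_query: int
    n_bg_pos: int
    n_bg: int
    fold_enrichment: float
    p: float  # NaN when undefined (flagged)
    undefined: bool = False

    def __post_init__(self) -> None:
        if self.n_query_pos > self.n_query or self.n_bg_pos > self.n_bg:
            raise ConfigurationError("positive counts exceed totals")

    @property
    def pct_observed(self) -> float:
        return self.n_query_pos / self.n_query if self.n_query else 0.0

    @property
    def pct_background(self) -> float:
        return self.n_bg_pos / self.n_bg if self.n_bg else 0.0


def hypergeom_upper_tail(n_query_pos: int, n_query: int, n_bg_pos: int, n_bg: int) -> float:
    """P(X >= n_query_pos), X ~ Hypergeom(N=n_bg, K=n_bg_pos, draws=n_query).

    The background is the population, so it must be at least as large as the
    query draw."""
    if n_query > n_bg:
        raise ConfigurationError(
            f"hypergeometric draws (n_query={n_query}) exceed the background "
            f"population (n_bg={n_bg}); enlarge the background"
        )
    return float(scipy.stats.hypergeom.sf(n_query_pos - 1, n_bg, n_bg_pos, n_query))


def test_motif_enrichment(
    query_peaks: Sequence[Peak],
    background_peaks: Sequence[Peak],
    occ: MotifOccurrenceMatrix,
    motif_names: Mapping[str, str] | None = None,
) -> list[MotifEnrichmentRecord]:
    """Hypergeometric motif over-representation in query vs background peaks.

    The background is the hypergeometric population (the convention of
    enrichment tools that compare DAPs against matched peaks).  A motif
    present in the query but absent from the background has undefined fold
    enrichment (+inf sentinel) and NA p, flagged for the caller.
    """
    if not query_peaks or not background_peaks:
        raise EmptyResultError("query and background peak sets must be non-empty")
    row = {p: i for i, p in enumerate(occ.peak_ids)}
    q_idx = [row[p.peak_id] for p in query_peaks]
    b_idx = [row[p.peak_id] for p in background_peaks]
    records = []
    for j, (mid) in enumerate(occ.motif_ids):
        n_q, n_b = len(q_idx), len(b_idx)
        q_pos = int(occ.indicators[q_idx, j].sum())
        b_pos = int(occ.indicators[b_idx, j].sum())
        if b_pos == 0:
            if q_pos > 0:
                fold, p, undef = float("inf"), float("nan"), True
            else:
                fold, p, undef = 0.0, 1.0, False
        else:
            fold = (q_pos / n_q) / (b_pos / n_b)
            p = hypergeom_upper_tail(q_pos, n_q, b_pos, n_b)
            undef = False
        name = motif_names.get(mid, mid) if motif_names else mid
        records.append(
            MotifEnrichmentRecord(mid, name, q_pos, n_q, b_pos, n_b, fold, p, undef)
        )
    return records


def rank_motifs(
    records: Sequence[MotifEnrichmentRecord],
    fold_min: float = 0.5,
    alpha: float = 0.05,
) -> list[MotifEnrichmentRecord]:
    """Keep fold_enrichment > fold_min and p < alpha; sort by descending
    fold enrichment, ties by ascending p then motif id."""
    kept = [
        r
        for r in records
        if r.fold_enrichment > fold_min and not np.isnan(r.p) and r.p < alpha
    ]
    kept.sort(key=lambda r: (-r.fold_enrichment, r.p, r.motif_id))
    return kept


# ---------------------------------------------------------------------------
# motif name -> TF gene mapping
# ---------------------------------------------------------------------------

def motif_names_to_genes(
    motif_names: Sequence[str], gene_ids: Sequence[str]
) -> dict[str, list[str]]:
    """Case-insensitive match of motif names to gene symbols; heterodimer
    names are split on '::' into their component TFs."""
    by_lower = {}
    for g in gene_ids:
        by_lower.setdefault(g.lower(), g)
    out: dict[str, list[str]] = {}
    for name in motif_names:
        parts = [p.strip() for p in name.split("::")]
        out[name] = sorted({by_lower[p.lower()] for p in parts if p.lower() in by_lower})
    return out
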