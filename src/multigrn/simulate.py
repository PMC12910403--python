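"""Synthetic paired-multiome generator with planted ground truth.

Emulates a spinal-cord-injury style experiment: neurons of four subtypes
sampled at three conditions (uninjured, 7 days post-injury, 2 months
post-injury), with

* subtype identity planted as disjoint marker-gene blocks in the RNA counts,
* condition-responsive accessibility planted as differentially accessible
  peaks (DAPs) per injury timepoint,
* a focal transcription factor whose expression rises at 7 dpi and returns
  to baseline by 2 mpi (the biphasic injury response),
* TF->target couplings planted by modulating each target gene's TSS-window
  accessibility rate with the TF's standardized expression, and
* a consensus motif planted into DAP sequences at a higher rate than into
  background peaks, over random-composition DNA with Beta-distributed GC.

RNA counts are negative binomial (Gamma-Poisson, shared dispersion); ATAC
counts are Poisson.  One global seed drives named sub-streams per generator
so adding a generator never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .exceptions import AlignmentError, ConfigurationError
from .io import (
    CountMatrix,
    Peak,
    PositionFrequencyMatrix,
    make_cell_table,
    write_cell_table,
    write_count_matrix,
    write_fasta,
    write_jaspar_pfms,
    write_peaks_bed,
)

_SUBSTREAM = {"rna": 0, "atac": 1, "sequences": 2}


@dataclass
class SimConfig:
    """All knobs of the simulation; defaults are the study-like conditions."""

    n_cells_per_subtype_per_condition: int = 50
    n_subtypes: int = 4
    conditions: tuple[str, ...] = ("uninjured", "7dpi", "2mpi")
    n_genes: int = 1000
    n_peaks: int = 1000
    nb_dispersion: float = 0.3
    baseline_mean: float = 1.0
    marker_fold: float = 8.0
    n_markers_per_subtype: int = 25
    n_dap_per_condition: int = 100
    dap_fold: float = 4.0
    atac_baseline_rate: float = 0.5
    tss_baseline_rate: float = 1.0
    planted_tf_ids: tuple[str, ...] = ("Creb5",)
    focal_tf_fold: float = 4.0
    planted_targets_per_tf: int = 30
    coupling_beta: float = 1.0  # gives planted-pair Spearman rho ~ 0.6 at n ~ 500
    motif_length: int = 8
    motif_planting_rate_dap: float = 0.5
    motif_planting_rate_background: float = 0.05
    n_decoy_motifs: int = 3
    gc_beta_params: tuple[float, float] = (8.0, 9.0)
    missing_gc_fraction: float = 0.02
    peak_width: int = 300
    tss_window_bp: int = 2000
    n_other_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_cells_per_subtype_per_condition",
            "n_subtypes",
            "n_genes",
            "n_peaks",
            "peak_width",
            "tss_window_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("nb_dispersion", "baseline_mean", "atac_baseline_rate", "tss_baseline_rate"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("marker_fold", "dap_fold", "focal_tf_fold"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.coupling_beta < 0:
            raise ConfigurationError(f"coupling_beta must be non-negative, got {self.coupling_beta}")
        for name in (
            "motif_planting_rate_dap",
            "motif_planting_rate_background",
            "missing_gc_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.motif_length < 4:
            raise ConfigurationError(f"motif_length must be >= 4, got {self.motif_length}")
        if self.motif_length > self.peak_width:
            raise ConfigurationError(
                f"motif_length {self.motif_length} exceeds peak_width {self.peak_width}"
            )
        if any(p <= 0 for p in self.gc_beta_params):
            raise ConfigurationError(f"gc_beta_params must be positive, got {self.gc_beta_params}")
        if self.planted_targets_per_tf > self.n_genes:
            raise ConfigurationError(
                f"planted_targets_per_tf {self.planted_targets_per_tf} exceeds n_genes {self.n_genes}"
            )
        if len(self.conditions) < 1:
            raise ConfigurationError("conditions must be non-empty")
        if self.n_dap_per_condition < 0 or self.planted_targets_per_tf < 0:
            raise ConfigurationError("counts must be non-negative")
        needed = (
            self.n_subtypes * self.n_markers_per_subtype
            + len(self.planted_tf_ids)
            + self.n_decoy_motifs
        )
        if needed > self.n_genes:
            raise ConfigurationError(
                f"n_genes {self.n_genes} too small for {needed} marker/TF/decoy genes"
            )
        n_inj = max(0, len(self.conditions) - 1)
        if n_inj * self.n_dap_per_condition > self.n_peaks:
            raise ConfigurationError(
                f"n_peaks {self.n_peaks} too small for "
                f"{n_inj * self.n_dap_per_condition} planted DAPs"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_SUBSTREAM[stream],))
        )


@dataclass
class GroundTruth:
    """Planted answers, one field per downstream stage."""

    subtype_label: np.ndarray
    condition_label: np.ndarray
    cell_class: np.ndarray
    gene_ids: list[str]
    marker_genes: dict[str, list[str]]
    planted_dap_ids: dict[str, list[str]]
    planted_edge_list: list[tuple[str, str, float]]
    motif_positive_peak_ids: dict[str, list[str]] = field(default_factory=dict)
    focal_tf_id: str = ""

    def validate(self, peak_ids: list[str] | None = None) -> None:
        genes = set(self.gene_ids)
        for tf, target, _ in self.planted_edge_list:
            if tf not in genes or target not in genes:
                raise AlignmentError(f"planted edge ({tf}, {target}) references unknown features")
        if peak_ids is not None:
            known = set(peak_ids)
            for cond, ids in self.planted_dap_ids.items():
                extra = set(ids) - known
                if extra:
                    raise AlignmentError(f"planted DAPs for {cond} not among peaks: {sorted(extra)[:5]}")

    def to_json(self) -> str:
        payload = {
            "subtype_label": self.subtype_label.tolist(),
            "condition_label": self.condition_label.tolist(),
            "cell_class": self.cell_class.tolist(),
            "gene_ids": self.gene_ids,
            "marker_genes": self.marker_genes,
            "planted_dap_ids": self.planted_dap_ids,
            "planted_edge_list": [[t, g, b] for t, g, b in self.planted_edge_list],
            "motif_positive_peak_ids": self.motif_positive_peak_ids,
            "focal_tf_id": self.focal_tf_id,
        }
        return json.dumps(payload, indent=1)


# ---------------------------------------------------------------------------
# deterministic feature layouts
# ---------------------------------------------------------------------------

def gene_names(cfg: SimConfig) -> list[str]:
    """Gene id layout: planted TFs first, then decoy-motif genes, then the rest."""
    width = len(str(cfg.n_genes))
    names = [f"gene{str(i).zfill(width)}" for i in range(cfg.n_genes)]
    for i, tf in enumerate(cfg.planted_tf_ids):
        names[i] = tf
    return names


def peak_intervals(cfg: SimConfig) -> list[Peak]:
    """Peaks tile chr1 with fixed spacing; ids are ``chrom:start-end``."""
    gap = cfg.peak_width + 700
    return [Peak("chr1", i * gap, i * gap + cfg.peak_width) for i in range(cfg.n_peaks)]


def _marker_blocks(cfg: SimConfig, genes: list[str]) -> dict[str, list[str]]:
    """Disjoint marker blocks per subtype, placed after TF and decoy genes."""
    offset = len(cfg.planted_tf_ids) + cfg.n_decoy_motifs
    blocks: dict[str, list[str]] = {}
    for s in range(cfg.n_subtypes):
        lo = offset + s * cfg.n_markers_per_subtype
        blocks[f"subtype{s}"] = genes[lo : lo + cfg.n_markers_per_subtype]
    return blocks


# ---------------------------------------------------------------------------
# RNA
# ---------------------------------------------------------------------------

def generate_rna_counts(cfg: SimConfig) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Negative-binomial RNA counts with planted subtype markers and the
    biphasic focal-TF response (up at 7 dpi, back to baseline at 2 mpi)."""
    rng = cfg.rng("rna")
    genes = gene_names(cfg)
    n_neurons = cfg.n_cells_per_subtype_per_condition * cfg.n_subtypes * len(cfg.conditions)
    n_cells = n_neurons + cfg.n_other_cells

    subtype = np.empty(n_cells, dtype=object)
    condition = np.empty(n_cells, dtype=object)
    cell_class = np.empty(n_cells, dtype=object)
    i = 0
    for cond in cfg.conditions:
        for s in range(cfg.n_subtypes):
            j = i + cfg.n_cells_per_subtype_per_condition
            subtype[i:j] = f"subtype{s}"
            condition[i:j] = cond
            cell_class[i:j] = "Neurons"
            i = j
    if cfg.n_other_cells:
        subtype[i:] = "NA"
        cell_class[i:] = "Other"
        # spread non-neurons evenly over conditions
        condition[i:] = [cfg.conditions[k % len(cfg.conditions)] for k in range(cfg.n_other_cells)]

    mean = np.full((n_cells, cfg.n_genes), cfg.baseline_mean)
    markers = _marker_blocks(cfg, genes)
    gene_pos = {g: k for k, g in enumerate(genes)}
    for s, block in markers.items():
        rows = np.flatnonzero((subtype == s))
        cols = [gene_pos[g] for g in block]
        mean[np.ix_(rows, cols)] *= cfg.marker_fold

    focal = cfg.planted_tf_ids[0] if cfg.planted_tf_ids else ""
    if focal and len(cfg.conditions) >= 2:
        acute = cfg.conditions[1]  # biphasic: elevated only at the acute timepoint
        rows = np.flatnonzero((condition == acute) & (cell_class == "Neurons"))
        mean[rows, gene_pos[focal]] *= cfg.focal_tf_fold

    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, mean * cfg.nb_dispersion)
    counts = rng.poisson(lam)

    width = len(str(n_cells))
    cell_ids = [f"cell{str(k).zfill(width)}" for k in range(n_cells)]
    cm = CountMatrix(sp.csr_matrix(counts), cell_ids, genes, "RNA")

    dap_ids = _planted_daps(cfg)
    edges = _planted_edges(cfg, genes)
    gt = GroundTruth(
        subtype_label=subtype,
        condition_label=condition,
        cell_class=cell_class,
        gene_ids=genes,
        marker_genes=markers,
        planted_dap_ids=dap_ids,
        planted_edge_list=edges,
        focal_tf_id=focal,
    )
    gt.validate([p.peak_id for p in peak_intervals(cfg)])
    cells = make_cell_table(
        cell_ids, cell_class, subtype, condition, rna=np.asarray(counts.sum(axis=1)).ravel()
    )
    return cm, cells, gt


def _planted_daps(cfg: SimConfig) -> dict[str, list[str]]:
    """Disjoint DAP blocks per injury condition, deterministic in the layout."""
    peaks = peak_intervals(cfg)
    out: dict[str, list[str]] = {}
    for k, cond in enumerate(cfg.conditions[1:]):
        lo = k * cfg.n_dap_per_condition
        out[cond] = [p.peak_id for p in peaks[lo : lo + cfg.n_dap_per_condition]]
    return out


def _planted_edges(cfg: SimConfig, genes: list[str]) -> list[tuple[str, str, float]]:
    """Each planted TF couples to a block of target genes from the tail of the
    gene list (never markers, TFs or decoys)."""
    edges = []
    tail = cfg.n_genes
    for tf in cfg.planted_tf_ids:
        lo = tail - cfg.planted_targets_per_tf
        targets = genes[lo:tail]
        tail = lo
        if lo < cfg.n_subtypes * cfg.n_markers_per_subtype + len(cfg.planted_tf_ids) + cfg.n_decoy_motifs:
            raise ConfigurationError("n_genes too small for planted targets")
        edges.extend((tf, g, cfg.coupling_beta) for g in targets)
    return edges


# ---------------------------------------------------------------------------
# ATAC (peaks + TSS windows)
# ---------------------------------------------------------------------------

def generate_atac_counts(
    cfg: SimConfig, rna: CountMatrix, gt: GroundTruth
) -> tuple[CountMatrix, CountMatrix]:
    """Poisson peak and TSS-window counts.

    Planted DAPs get rate x ``dap_fold`` in their condition; for a planted
    edge (t, g), gene g's TSS rate is baseline x exp(beta * z_t) with z_t the
    standardized log1p RNA count of t in each cell (mean-corrected so the
    marginal rate stays at baseline — rank correlation is unaffected).
    """
    if len(gt.condition_label) != rna.n_cells:
        raise AlignmentError(
            f"ground truth describes {len(gt.condition_label)} cells but RNA has {rna.n_cells}"
        )
    rng = cfg.rng("atac")
    peaks = peak_intervals(cfg)
    peak_ids = [p.peak_id for p in peaks]
    peak_pos = {pid: i for i, pid in enumerate(peak_ids)}
    n_cells = rna.n_cells

    rate = np.full((n_cells, cfg.n_peaks), cfg.atac_baseline_rate)
    for cond, ids in gt.planted_dap_ids.items():
        rows = np.flatnonzero(gt.condition_label == cond)
        cols = [peak_pos[pid] for pid in ids]
        if cols:
            rate[np.ix_(rows, cols)] *= cfg.dap_fold
    peak_counts = rng.poisson(rate)

    tss_rate = np.full((n_cells, cfg.n_genes), cfg.tss_baseline_rate)
    gene_pos = {g: k for k, g in enumerate(gt.gene_ids)}
    rna_dense = rna.dense().astype(float)
    for tf, target, beta in gt.planted_edge_list:
        if beta == 0:
            continue
        x = np.log1p(rna_dense[:, gene_pos[tf]])
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        mult = np.exp(beta * z)
        tss_rate[:, gene_pos[target]] *= mult / mult.mean()
    tss_counts = rng.poisson(tss_rate)

    cm_peaks = CountMatrix(sp.csr_matrix(peak_counts), rna.cell_ids, peak_ids, "ATAC_PEAK")
    cm_tss = CountMatrix(sp.csr_matrix(tss_counts), rna.cell_ids, list(gt.gene_ids), "ATAC_TSS")
    return cm_peaks, cm_tss


# ---------------------------------------------------------------------------
# peak sequences + motifs
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _consensus_pfm(motif_id: str, name: str, consensus: str, depth: int = 20) -> PositionFrequencyMatrix:
    counts = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] += depth - 4
    return PositionFrequencyMatrix(motif_id, name, counts)


def generate_peak_sequences(
    cfg: SimConfig, gt: GroundTruth
) -> tuple[list[Peak], list[PositionFrequencyMatrix]]:
    """Random-composition DNA per peak with Beta-distributed GC; the planted
    consensus motif is inserted into DAPs at ``motif_planting_rate_dap`` and
    into other peaks at ``motif_planting_rate_background``.  A configurable
    fraction of peaks loses its GC metadata (the missing-GC exclusion path).

    The planted motif is named after the focal TF so motif->gene mapping
    recovers it; decoy motifs (named after non-differential genes) are never
    planted.
    """
    rng = cfg.rng("sequences")
    peaks = peak_intervals(cfg)
    dap_ids = set().union(*gt.planted_dap_ids.values()) if gt.planted_dap_ids else set()

    a, b = cfg.gc_beta_params
    gc_draw = rng.beta(a, b, size=len(peaks))
    consensus = "".join(rng.choice(_BASES, size=cfg.motif_length))

    planted: list[str] = []
    out: list[Peak] = []
    for peak, gc in zip(peaks, gc_draw):
        L = peak.length
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seq = rng.choice(_BASES, size=L, p=p)
        is_dap = peak.peak_id in dap_ids
        rate = cfg.motif_planting_rate_dap if is_dap else cfg.motif_planting_rate_background
        if rng.random() < rate:
            off = int(rng.integers(0, L - cfg.motif_length + 1))
            seq[off : off + cfg.motif_length] = list(consensus)
            planted.append(peak.peak_id)
        s = "".join(seq)
        gc_obs: float | None = (s.count("G") + s.count("C")) / L
        out.append(Peak(peak.chrom, peak.start, peak.end, peak.peak_id, gc_obs, s))

    if cfg.missing_gc_fraction > 0:
        n_missing = int(round(cfg.missing_gc_fraction * len(out)))
        for i in rng.choice(len(out), size=n_missing, replace=False):
            out[i].gc_fraction = None

    motif_name = gt.focal_tf_id or "motif0"
    pfms = [_consensus_pfm("SYN0001.1", motif_name, consensus)]
    decoy_names = [g for g in gt.gene_ids[len(cfg.planted_tf_ids):len(cfg.planted_tf_ids) + cfg.n_decoy_motifs]]
    for k, name in enumerate(decoy_names, start=2):
        decoy = "".join(rng.choice(_BASES, size=cfg.motif_length))
        pfms.append(_consensus_pfm(f"SYN{k:04d}.1", name, decoy))
    gt.motif_positive_peak_ids = {pfms[0].motif_id: planted}
    return out, pfms


# ---------------------------------------------------------------------------
# one-call simulation + writers
# ---------------------------------------------------------------------------

@dataclass
class Simulation:
    cfg: SimConfig
    rna: CountMatrix
    atac_peaks: CountMatrix
    atac_tss: CountMatrix
    cells: pd.DataFrame
    peaks: list[Peak]
    pfms: list[PositionFrequencyMatrix]
    truth: GroundTruth


def simulate(cfg: SimConfig) -> Simulation:
    """Run all three generators under one seed and return the bundle."""
    rna, cells, gt = generate_rna_counts(cfg)
    atac_peaks, atac_tss = generate_atac_counts(cfg, rna, gt)
    peaks, pfms = generate_peak_sequences(cfg, gt)
    cells["total_counts_atac_peak"] = np.asarray(atac_peaks.values.sum(axis=1)).ravel()
    cells["total_counts_atac_tss"] = np.asarray(atac_tss.values.sum(axis=1)).ravel()
    return Simulation(cfg, rna, atac_peaks, atac_tss, cells, peaks, pfms, gt)


def write_simulation(sim: Simulation, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_count_matrix(sim.rna, outdir / "rna")
    write_count_matrix(sim.atac_peaks, outdir / "atac_peak")
    write_count_matrix(sim.atac_tss, outdir / "atac_tss")
    write_cell_table(sim.cells, outdir / "cells.tsv")
    write_peaks_bed(sim.peaks, outdir / "peaks.bed")
    write_fasta({p.peak_id: p.sequence for p in sim.peaks if p.sequence}, outdir / "peaks.fasta")
    write_jaspar_pfms(sim.pfms, outdir / "motifs.jaspar")
    (outdir / "ground_truth.json").write_text(sim.truth.to_json())
    (outdir / "sim_config.json").write_text(
        json.dumps(dataclasses.asdict(sim.cfg), indent=1, default=list)
    )
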