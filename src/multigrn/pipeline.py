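"""End-to-end orchestration: simulate -> preprocess -> differential features
-> motif enrichment -> prioritization -> TF-gene network, under one config
and one seed, producing a run directory with per-stage outputs, a JSON
summary of stage counts, and a log file."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diff, motifs, network, preprocess, prioritize
from .exceptions import ConfigurationError, MultigrnError
from .io import write_cell_table, write_network
from .simulate import SimConfig, Simulation, simulate, write_simulation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config for the whole run; thresholds default to the analysis
    constants (accessibility fraction > 20%, adjusted p < 0.05,
    fold-enrichment > 0.5, |r| > 0.3, p < 0.05, top 20 targets)."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_pct: float = 0.20
    alpha_adj: float = 0.05
    fold_min: float = 0.5
    alpha_motif: float = 0.05
    r_min: float = 0.3
    alpha_edge: float = 0.05
    top_k: int = 20
    min_counts: float = 1
    min_features: int = 1
    n_components: int = 30
    resolution: float = 0.5
    n_neighbors: int = 15
    gc_matched_background: bool = True
    n_background: int | None = None  # None -> same size as the GC pool allows (min(4x query, pool))
    network_condition: str | None = None  # None pools all neurons
    focal_tf: str | None = None  # None -> top prioritized candidate
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("min_pct", 0, 1),
            ("alpha_adj", 0, 1),
            ("alpha_motif", 0, 1),
            ("alpha_edge", 0, 1),
            ("r_min", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigurationError(f"{name}={v} outside [{lo}, {hi}]")
        if self.top_k < 1:
            raise ConfigurationError(f"top_k must be >= 1, got {self.top_k}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        bad = set(raw) - known
        if bad:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(bad)}")
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        bad = set(sim_raw) - sim_known
        if bad:
            raise ConfigurationError(f"unknown sim config keys: {sorted(bad)}")
        if "conditions" in sim_raw:
            sim_raw["conditions"] = tuple(sim_raw["conditions"])
        for tup in ("planted_tf_ids", "gc_beta_params"):
            if tup in sim_raw:
                sim_raw[tup] = tuple(sim_raw[tup])
        cfg = cls(sim=SimConfig(**sim_raw), **raw)
        return cfg


def run_pipeline(config: PipelineConfig, outdir, sim: Simulation | None = None) -> dict:
    """Execute all stages in dependency order; returns the summary dict.

    A stage failure raises with the failing stage named; outputs of
    completed stages remain in ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("multigrn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "simulate"
    try:
        t0 = time.time()
        if sim is None:
            config.sim = dataclasses.replace(config.sim, seed=config.seed)
            sim = simulate(config.sim)
        write_simulation(sim, outdir / "simulate")
        summary["stages"]["simulate"] = {
            "n_cells": sim.rna.n_cells,
            "n_genes": sim.rna.n_features,
            "n_peaks": len(sim.peaks),
            "n_motifs": len(sim.pfms),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "preprocess"
        t0 = time.time()
        rna, cells = preprocess.subset_neurons(sim.rna, sim.cells)
        rna, cells = preprocess.filter_cells(rna, cells, config.min_counts, config.min_features)
        keep = set(cells["cell_id"])
        mask = np.asarray([c in keep for c in sim.atac_peaks.cell_ids])
        atac_peak = sim.atac_peaks.subset_cells(mask)
        atac_tss = sim.atac_tss.subset_cells(mask)
        rna_norm = preprocess.lognormalize_rna(rna)
        peak_norm = preprocess.tfidf_normalize_atac(atac_peak)
        tss_norm = preprocess.tfidf_normalize_atac(atac_tss)
        pca = preprocess.run_pca(rna_norm, n_components=config.n_components)
        labels = preprocess.cluster_cells(
            pca, resolution=config.resolution, n_neighbors=config.n_neighbors, seed=config.seed
        )
        cells = cells.assign(cluster=labels)
        write_cell_table(cells, outdir / "cells_clustered.tsv")
        summary["stages"]["preprocess"] = {
            "n_neurons": rna.n_cells,
            "n_clusters": int(labels.max()) + 1,
            "pca_components_dropped": pca.components_dropped,
            "seconds": round(time.time() - t0, 2),
        }

        stage = "diff"
        t0 = time.time()
        peaks_by_id = {p.peak_id: p for p in sim.peaks}
        timepoints = [c for c in config.sim.conditions if c != "uninjured"]
        daps: dict[str, list] = {}
        degs: dict[str, list] = {}
        for tp in timepoints:
            d = diff.find_differential_features(
                peak_norm, cells, tp, min_pct=config.min_pct, alpha_adj=config.alpha_adj
            )
            daps[tp] = diff.exclude_missing_gc(d, peaks_by_id)
            degs[tp] = diff.find_differential_features(
                rna_norm, cells, tp, min_pct=config.min_pct, alpha_adj=config.alpha_adj
            )
            diff.results_to_frame(daps[tp]).to_csv(outdir / f"daps_{tp}.tsv", sep="\t", index=False)
            diff.results_to_frame(degs[tp]).to_csv(outdir / f"degs_{tp}.tsv", sep="\t", index=False)
            summary["stages"].setdefault("diff", {})[tp] = {
                "n_daps_raw": len(d),
                "n_daps": len(daps[tp]),
                "n_degs": len(degs[tp]),
            }
        summary["stages"]["diff"]["seconds"] = round(time.time() - t0, 2)

        stage = "motifs"
        t0 = time.time()
        occ = motifs.scan_peaks(sim.peaks, sim.pfms)
        names = {m.motif_id: m.motif_name for m in sim.pfms}
        enriched: dict[str, list] = {}
        for tp in timepoints:
            dap_ids = {r.feature_id for r in daps[tp]}
            query = [p for p in sim.peaks if p.peak_id in dap_ids and p.gc_fraction is not None]
            pool = [p for p in sim.peaks if p.peak_id not in dap_ids and p.gc_fraction is not None]
            if not query:
                enriched[tp] = []
                continue
            bg = pool
            if config.gc_matched_background:
                n_bg = motifs.feasible_background_size(
                    query, pool, config.n_background or 4 * len(query)
                )
                if n_bg >= len(query):
                    bg = motifs.match_background_by_gc(query, pool, n_bg, seed=config.seed)
                else:
                    logger.warning(
                        "GC-matched background infeasible at query size %d for %s; "
                        "using the full non-DAP pool", len(query), tp,
                    )
            recs = motifs.test_motif_enrichment(query, bg, occ, motif_names=names)
            enriched[tp] = motifs.rank_motifs(recs, config.fold_min, config.alpha_motif)
            summary["stages"].setdefault("motifs", {})[tp] = {
                "n_query": len(query),
                "n_background": len(bg),
                "n_enriched": len(enriched[tp]),
            }
        summary["stages"].setdefault("motifs", {})["seconds"] = round(time.time() - t0, 2)

        stage = "prioritize"
        t0 = time.time()
        cand_by_tp: dict[str, list] = {}
        for tp in timepoints:
            inter, venn = prioritize.intersect_motifs_degs(enriched[tp], degs[tp])
            fold_by_gene: dict[str, float] = {}
            for m in enriched[tp]:
                for g in motifs.motif_names_to_genes([m.motif_name], sorted(inter))[m.motif_name]:
                    fold_by_gene[g] = max(fold_by_gene.get(g, 0.0), m.fold_enrichment)
            direction = {r.feature_id: r.direction for r in degs[tp]}
            cand_by_tp[tp] = [(g, fold_by_gene[g], direction.get(g, "up")) for g in sorted(inter)]
            summary["stages"].setdefault("prioritize", {})[tp] = {"venn": venn}
        candidates = prioritize.prioritize_across_timepoints(cand_by_tp) if cand_by_tp else []
        summary["stages"].setdefault("prioritize", {})["n_candidates"] = len(candidates)
        if candidates:
            summary["stages"]["prioritize"]["top_tf"] = candidates[0].tf
        summary["stages"]["prioritize"]["seconds"] = round(time.time() - t0, 2)

        stage = "network"
        t0 = time.time()
        tf_universe = sorted(
            {
                g
                for name in names.values()
                for g in motifs.motif_names_to_genes([name], rna_norm.feature_ids)[name]
            }
        )
        diff_tfs: set[str] = set()
        for tp in timepoints:
            try:
                res = diff.find_differential_tfs(
                    rna_norm, cells, tf_universe, tp,
                    min_pct=config.min_pct, alpha_adj=config.alpha_adj,
                )
            except MultigrnError:
                res = []
            diff_tfs |= {r.feature_id for r in res}
        focal = config.focal_tf or (candidates[0].tf if candidates else None)
        if focal:
            diff_tfs.add(focal)
        tf_list = sorted(diff_tfs)
        if config.network_condition is not None:
            sel = (cells["condition"].astype(str) == config.network_condition).to_numpy()
            rna_net = rna_norm.subset_cells(sel)
            tss_net = tss_norm.subset_cells(sel)
        else:
            rna_net, tss_net = rna_norm, tss_norm
        net = network.build_tf_gene_network(
            tf_list,
            tss_net.feature_ids,
            rna_net,
            tss_net,
            r_min=config.r_min,
            alpha=config.alpha_edge,
        )
        write_network(net, outdir / "network_edges.tsv", "edge_tsv")
        write_network(net, outdir / "network.graphml", "graphml")
        summary["stages"]["network"] = {
            "n_candidate_tfs": len(tf_list),
            "n_edges": net.n_edges,
        }
        if focal and focal in net.tf_nodes:
            sub = network.focal_tf_subnetwork(net, focal, k=config.top_k)
            write_network(sub, outdir / f"subnetwork_{focal}.tsv", "edge_tsv")
            nodes_df, edges_df = network.export_network_plot_data(sub)
            nodes_df.to_csv(outdir / "subnetwork_nodes.tsv", sep="\t", index=False)
            edges_df.to_csv(outdir / "subnetwork_edges.tsv", sep="\t", index=False)
            summary["stages"]["network"]["focal_tf"] = focal
            summary["stages"]["network"]["focal_subnetwork_size"] = sub.n_edges
        summary["stages"]["network"]["seconds"] = round(time.time() - t0, 2)
    except Exception:
        logger.exception("pipeline failed in stage %r", stage)
        summary["failed_stage"] = stage
        (outdir / "summary.json").write_text(_stable_json(summary))
        root.removeHandler(handler)
        handler.close()
        raise MultigrnError(f"pipeline failed in stage {stage!r}")
    # timing is environment noise; keep it in the log, not the summary
    deterministic = _strip_seconds(summary)
    (outdir / "summary.json").write_text(_stable_json(deterministic))
    root.removeHandler(handler)
    handler.close()
    return deterministic


def _strip_seconds(obj):
    if isinstance(obj, dict):
        return {k: _strip_seconds(v) for k, v in obj.items() if k != "seconds"}
    return obj


def _stable_json(obj) -> str:
    return json.dumps(obj, indent=1, sort_keys=True)
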