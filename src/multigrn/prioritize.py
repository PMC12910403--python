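"""Candidate-TF prioritization: intersect enriched-motif TFs with
upregulated DEGs per timepoint, then rank TFs that recur across the acute
(7 dpi) and chronic (2 mpi) phases above single-phase hits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .diff import DifferentialFeatureResult
from .exceptions import ConfigurationError
from .motifs import MotifEnrichmentRecord, motif_names_to_genes


@dataclass
class CandidateTF:
    tf: str
    timepoints_enriched: tuple[str, ...]
    fold_enrichment_by_timepoint: dict[str, float]
    deg_direction_by_timepoint: dict[str, str]
    priority_rank: int = 0

    def __post_init__(self) -> None:
        if not self.timepoints_enriched:
            raise ConfigurationError(f"candidate {self.tf} has no enriched timepoints")

    @property
    def mean_fold(self) -> float:
        return float(np.mean(list(self.fold_enrichment_by_timepoint.values())))


def intersect_motifs_degs(
    enriched_motifs: Sequence[MotifEnrichmentRecord],
    deg_list: Sequence[DifferentialFeatureResult],
    upregulated_only: bool = True,
) -> tuple[set[str], dict[str, int]]:
    """TF genes both motif-enriched and differentially expressed.

    Motif names are mapped to DEG gene ids case-insensitively (heterodimers
    split on '::'); by default only upregulated DEGs are intersected.
    Returns the intersection and the Venn counts
    {n_motif_tfs, n_degs, n_intersection}.
    """
    degs = [r for r in deg_list if (r.direction == "up" or not upregulated_only)]
    deg_ids = {r.feature_id for r in degs}
    mapping = motif_names_to_genes([m.motif_name for m in enriched_motifs], sorted(deg_ids))
    motif_tfs_in_universe = {g for genes in mapping.values() for g in genes}
    # motif TF count on the gene scale: one per distinct mappable TF name part
    all_parts = {p.strip().lower() for m in enriched_motifs for p in m.motif_name.split("::")}
    inter = motif_tfs_in_universe & deg_ids
    counts = {
        "n_motif_tfs": len(all_parts),
        "n_degs": len(deg_ids),
        "n_intersection": len(inter),
    }
    return inter, counts


def prioritize_across_timepoints(
    candidates_by_timepoint: Mapping[str, Sequence[tuple[str, float, str]]],
) -> list[CandidateTF]:
    """Rank candidate TFs across timepoints.

    ``candidates_by_timepoint`` maps a timepoint label to (tf,
    fold_enrichment, deg_direction) triples.  TFs present at every supplied
    timepoint outrank TFs present at a subset; within a tier, descending
    mean fold enrichment; deterministic tie-break by id.  ``priority_rank``
    is 1-based.
    """
    if not candidates_by_timepoint:
        raise ConfigurationError("at least one timepoint required")
    per_tf: dict[str, dict[str, tuple[float, str]]] = {}
    for tp, entries in candidates_by_timepoint.items():
        for tf, fold, direction in entries:
            per_tf.setdefault(tf, {})[tp] = (float(fold), direction)
    out = []
    for tf, by_tp in per_tf.items():
        out.append(
            CandidateTF(
                tf=tf,
                timepoints_enriched=tuple(sorted(by_tp)),
                fold_enrichment_by_timepoint={tp: v[0] for tp, v in by_tp.items()},
                deg_direction_by_timepoint={tp: v[1] for tp, v in by_tp.items()},
            )
        )
    out.sort(key=lambda c: (-len(c.timepoints_enriched), -c.mean_fold, c.tf))
    for rank, c in enumerate(out, start=1):
        c.priority_rank = rank
    return out
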