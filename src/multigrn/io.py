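"""Readers, writers and in-memory containers for every on-disk format the
pipeline touches.

Conventions
-----------
* Count matrices are held cells x features in memory (analysis orientation).
  On disk, MatrixMarket files are features x cells with ``features.tsv`` /
  ``barcodes.tsv`` sidecars, the layout emitted by the common droplet
  pipelines; orientation is converted at the boundary.
* Genomic intervals are 0-based half-open internally; BED is read and
  written unchanged.  The 1-based MatrixMarket indexing is handled by
  :mod:`scipy.io`.
* All text files are UTF-8 and tab-delimited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import FormatError

MODALITIES = ("RNA", "ATAC_PEAK", "ATAC_TSS")
CONDITIONS = ("uninjured", "7dpi", "2mpi")

_DNA = set("ACGTN")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A sparse cells x features matrix with one modality tag.

    ``values`` holds raw non-negative counts until a normalizer sets
    ``normalized``; ids are unique strings aligned with the matrix axes.
    """

    values: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        n, m = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(f"matrix has {n} rows but {len(self.cell_ids)} cell ids")
        if m != len(self.feature_ids):
            raise FormatError(f"matrix has {m} columns but {len(self.feature_ids)} feature ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("duplicate feature ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative entries in count matrix")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in lookup]
        if missing:
            raise KeyError(f"features not in matrix: {missing[:5]}")
        return np.asarray([lookup[f] for f in ids], dtype=int)

    def subset_cells(self, mask_or_index: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.values[idx],
            [self.cell_ids[i] for i in idx],
            self.feature_ids,
            self.modality,
            self.normalized,
        )

    def subset_features(self, ids: Sequence[str]) -> "CountMatrix":
        idx = self.feature_index(ids)
        return CountMatrix(
            self.values[:, idx],
            self.cell_ids,
            [self.feature_ids[i] for i in idx],
            self.modality,
            self.normalized,
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def make_cell_table(
    cell_ids: Sequence[str],
    cell_class: Sequence[str],
    neuron_subtype: Sequence[str],
    condition: Sequence[str],
    **total_counts: Sequence[float],
) -> pd.DataFrame:
    """Assemble the per-cell metadata table.

    Columns: ``cell_id``, ``cell_class`` ("Neurons" vs other),
    ``neuron_subtype``, ``condition`` (closed set) plus optional
    ``total_counts_<modality>`` columns.
    """
    cell_ids = list(cell_ids)
    if len(set(cell_ids)) != len(cell_ids):
        raise FormatError("duplicate cell ids in cell table")
    bad = sorted(set(condition) - set(CONDITIONS))
    if bad:
        raise FormatError(f"conditions outside {CONDITIONS}: {bad}")
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "cell_class": list(cell_class),
            "neuron_subtype": list(neuron_subtype),
            "condition": pd.Categorical(condition, categories=CONDITIONS),
        }
    )
    for key, vals in total_counts.items():
        df[f"total_counts_{key.lower()}"] = np.asarray(vals)
    return df


@dataclass
class Peak:
    """A genomic interval (0-based half-open) with optional GC and sequence."""

    chrom: str
    start: int
    end: int
    peak_id: str = ""
    gc_fraction: float | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"peak start {self.start} >= end {self.end}")
        if not self.peak_id:
            self.peak_id = f"{self.chrom}:{self.start}-{self.end}"
        if self.gc_fraction is not None and not (0.0 <= self.gc_fraction <= 1.0):
            raise FormatError(f"gc_fraction {self.gc_fraction} outside [0, 1]")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if set(self.sequence) - _DNA:
                raise FormatError(f"non-ACGTN characters in sequence of {self.peak_id}")
            if len(self.sequence) != self.end - self.start:
                raise FormatError(
                    f"sequence length {len(self.sequence)} != interval length "
                    f"{self.end - self.start} for {self.peak_id}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PositionFrequencyMatrix:
    """Nucleotide counts per motif column; rows ordered A, C, G, T."""

    motif_id: str
    motif_name: str
    counts: np.ndarray  # 4 x L

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"PFM {self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 1:
            raise FormatError(f"PFM {self.motif_id}: zero-length motif")
        if (self.counts < 0).any():
            raise FormatError(f"PFM {self.motif_id}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise FormatError(f"PFM {self.motif_id}: zero column sum")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


# ---------------------------------------------------------------------------
# count matrices (MatrixMarket + sidecars)
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    ids = [line.split("\t")[0].strip() for line in path.read_text().splitlines() if line.strip()]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate ids in {path}")
    return ids


def read_count_matrix(mtx_path, features_path, barcodes_path, modality: str) -> CountMatrix:
    """Read a features x cells MatrixMarket triplet into a cells x features matrix."""
    mtx_path, features_path, barcodes_path = Path(mtx_path), Path(features_path), Path(barcodes_path)
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # pragma: no cover - scipy's message is opaque
        raise FormatError(f"cannot parse MatrixMarket file {mtx_path}: {exc}") from exc
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    mat = sp.csr_matrix(mat).T  # disk: features x cells -> memory: cells x features
    if mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"{mtx_path}: matrix is {mat.T.shape} (features x cells) but sidecars list "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    return CountMatrix(mat, barcodes, features, modality)


def write_count_matrix(cm: CountMatrix, outdir) -> None:
    """Write ``matrix.mtx`` (features x cells) + ``features.tsv`` + ``barcodes.tsv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(cm.values.T))
    (outdir / "features.tsv").write_text("".join(f"{f}\n" for f in cm.feature_ids))
    (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in cm.cell_ids))


def read_count_matrix_dir(indir, modality: str) -> CountMatrix:
    indir = Path(indir)
    return read_count_matrix(
        indir / "matrix.mtx", indir / "features.tsv", indir / "barcodes.tsv", modality
    )


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    required = {"cell_id", "cell_class", "neuron_subtype", "condition"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return make_cell_table(
        df["cell_id"],
        df["cell_class"],
        df["neuron_subtype"],
        df["condition"],
        **{
            c.removeprefix("total_counts_"): df[c]
            for c in df.columns
            if c.startswith("total_counts_")
        },
    )


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_peaks_bed(path) -> list[Peak]:
    """Parse BED (>=3 columns, 0-based half-open); column 4 is the peak id,
    column 5 (score) carries the GC fraction when numeric, '.' when missing."""
    peaks: list[Peak] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if start >= end:
            raise FormatError(f"{path}:{ln}: start {start} >= end {end}")
        name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
        gc: float | None = None
        if len(fields) > 4 and fields[4] != ".":
            gc = float(fields[4])
        peaks.append(Peak(chrom, start, end, peak_id=name, gc_fraction=gc))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            gc = "." if p.gc_fraction is None else f"{p.gc_fraction:.6g}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{gc}\t+\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map; multi-line records joined."""
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id}")
        seq = str(rec.seq).upper()
        if set(seq) - _DNA:
            raise FormatError(f"{path}: non-ACGTN characters in record {rec.id}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text
# ---------------------------------------------------------------------------

def read_jaspar_pfms(path) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR-format PFM blocks (``>id name`` header + 4 base rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:
            raise FormatError(f"cannot parse JASPAR file {path}: {exc}") from exc
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(
            PositionFrequencyMatrix(
                motif_id=m.matrix_id or m.name, motif_name=m.name or m.matrix_id, counts=counts
            )
        )
    if not out:
        raise FormatError(f"{path}: no motifs found")
    return out


def write_jaspar_pfms(pfms: Iterable[PositionFrequencyMatrix], path) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id}\t{pfm.motif_name}\n")
            for base, row in zip("ACGT", pfm.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base}  [ {cells} ]\n")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(network, path, format: str = "edge_tsv") -> None:
    """Write a regulatory network as an edge TSV (tf, target, rho, p) or GraphML."""
    edges = network.edges if hasattr(network, "edges") else list(network)
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("tf\ttarget\trho\tp\n")
            for e in edges:
                fh.write(f"{e.tf}\t{e.target}\t{e.rho:.6g}\t{e.p:.6g}\n")
    elif format == "graphml":
        g = nx.DiGraph()
        for e in edges:
            g.add_node(e.tf, role="TF")
            if e.target not in g:
                g.add_node(e.target, role="target")
            g.add_edge(e.tf, e.target, rho=float(e.rho), p=float(e.p))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"tf", "target", "rho", "p"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df
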