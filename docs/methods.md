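# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic-data validation does and does not establish.

## Synthetic paired multiome

The generator emulates a single-cell multiome of spinal-cord neurons with
four subtypes sampled at three conditions (uninjured, 7 dpi, 2 mpi). One
global seed drives three named sub-streams (RNA, ATAC, sequences), so adding
a generator never perturbs earlier draws and identical configs are
byte-reproducible.

**RNA.** Counts are negative binomial via the Gamma–Poisson mixture:
λ ~ Gamma(1/φ, μφ), count ~ Poisson(λ), with a single dispersion φ shared
across genes (default 0.3) — the standard scRNA-seq noise model, kept
deliberately simple so nulls stay analytically transparent. Baseline mean is
1.0 per gene. Each subtype owns a disjoint block of marker genes (default 25)
whose mean is multiplied by `marker_fold` (default 8, a strong-separation
regime). The focal TF (default gene id `Creb5`) follows the biphasic injury
response: mean × `focal_tf_fold` (default 4) at the acute timepoint only,
baseline again at the chronic one.

**ATAC.** Peak and TSS-window counts are Poisson — scATAC counts are sparse
and near-binary, and omitting zero-inflation keeps every null distribution
exact. Baseline peak rate 0.5 (detection ≈ 39 % of cells, comfortably above
the 20 % accessibility-fraction filter); planted DAPs get rate ×
`dap_fold` (default 4) in their condition only, with disjoint DAP blocks per
injury timepoint. For each planted edge (t, g), gene g's TSS-window rate is
baseline × exp(β·z_t)/E[exp(β·z_t)], where z_t is the standardized log1p RNA
count of t per cell. The mean-correction keeps the marginal rate at baseline
without affecting rank correlation. Coupling is injected through TSS windows
(not peaks) because the network stage correlates TF expression with TSS
accessibility. β defaults to 1.0, calibrated once so that planted pairs show
empirical Spearman ρ ≈ 0.6 at ~500 cells; the relationship saturates above
β ≈ 1.5 as Poisson ties dominate, so monotonicity checks use the 0.2–1.0
range.

**Sequences.** Per-peak GC is drawn from Beta(8, 9) (mean ≈ 0.47, a
realistic peak-GC spread); bases are iid with P(G) = P(C) = gc/2. A random
consensus k-mer (default length 8) is overwritten at a uniform offset into
`motif_planting_rate_dap` of planted DAPs (default 0.5) and
`motif_planting_rate_background` of other peaks (default 0.05). The planted
motif's PFM is built from the consensus with +1 pseudocounts and carries the
focal TF's name, so motif→gene mapping can recover it; a few decoy PFMs
named after non-differential genes are generated but never planted. A
configurable 2 % of peaks loses its GC metadata to exercise the missing-GC
exclusion rule without dominating.

What the generator does **not** model: fragment-level ATAC structure,
doublets, batch effects, ambient RNA, gene-length or GC bias in RNA,
zero-inflation, and cross-gene correlation beyond the planted structure.
Passing tests therefore demonstrate correctness of the *procedure* under a
clean generative model, not robustness to every artifact of real data.

## Preprocessing

RNA: value = log1p(count / cell_total × 10⁴). ATAC: TF-IDF in the common
scATAC "log1p(tf·idf·scale)" variant, tf = count/cell_total, idf =
n_cells/n_cells_with_feature, scale 10⁴. Both preserve the zero pattern and
are feature-permutation equivariant (property-tested). Cells with zero total
counts are an error, reported by id.

LSI is a truncated SVD (ARPACK) of the TF-IDF matrix; PCA centers and
unit-scales first. Component signs are fixed by making each component's
largest-|loading| cell positive, so embeddings are deterministic, and tests
compare absolute correlations where sign is not meaningful. Any component
with |Pearson r| > 0.9 against per-cell total counts is flagged
depth-driven and excluded from `usable` coordinates — standard scATAC
practice. Note that TF-IDF itself removes most depth signal; the flag
matters mainly when embedding un-depth-normalized input.

Clustering is Leiden (RBConfiguration, seeded, 2 iterations) on a
shared-nearest-neighbor graph: kNN (k = 15, self included), edges weighted
by neighborhood Jaccard overlap, weak edges (< 1/15) pruned. The resolution
default is 0.5, chosen so that a single homogeneous blob of up to ~500 cells
stays at ≤ 2 clusters while strongly separated planted subtypes — which form
disconnected SNN components that modularity can never merge — are recovered
exactly. At γ = 1.0 a homogeneous blob of a few hundred cells fragments into
~5 communities (modularity's √m community scale), which misrepresents null
data; 0.5 trades fine substructure sensitivity for null stability. Labels
are relabeled by decreasing cluster size for determinism.

## Differential features

Per-feature Wilcoxon rank-sum on normalized values. Exact p by enumeration
of the permutation distribution when n₁+n₂ ≤ 12 with no ties (two-sided p =
P(|U−μ| ≥ |u−μ|)); otherwise the normal approximation with tie and
continuity correction — at single-cell group sizes the asymptotic branch is
the one that runs, and a vectorized column-wise implementation keeps
1,000-feature × hundreds-of-cells scans fast.

The order is fixed as **filter → test → adjust**: features where neither
group exceeds `min_pct` = 0.20 nonzero cells are excluded *before* testing,
and Benjamini–Hochberg runs over the tested set only (a regression test pins
this, since the adjusted values differ if the order changes). The
accessibility fraction is interpreted as max of the two group fractions,
matching the `min.pct` semantics of the common marker-finding tools. BH was
chosen for "adjusted p-value"; log2 fold change uses expm1-ed group means
with pseudocount 1 (explicit because normalized-scale means need a
convention). DAPs whose peak lacks GC metadata are excluded afterwards, with
the removal count logged.

A known property of depth normalization on these synthetic data: planting
many DAPs upward in one condition inflates that condition's cell totals, so
*non*-DAP peaks shift slightly downward after normalization and can reach
significance as "down" features (a compositional effect, familiar from
differential-abundance analysis). Planted DAPs are still recovered with
direction "up" at ≥ 90 %; downstream stages are insensitive because motif
enrichment measures over-representation against background and
prioritization intersects with *upregulated* genes.

## Motif annotation and enrichment

PFM → PWM: log2 of (count + 0.8·bg) / (colsum + 0.8) over background
frequency (uniform by default); pseudocount 0.8 split by background is a
common scanning default, configurable. A peak is motif-positive if any
window on either strand reaches the threshold, default 80 % of the motif's
maximum bit score. Reverse-strand hits are computed by scanning the
reverse-complement PWM and reported in forward coordinates; N bases score 0
bits (background-neutral).

Enrichment: one-sided hypergeometric upper tail with the background sample
as population — P(X ≥ k), X ~ Hypergeom(N = n_bg, K = n_bg⁺, draws =
n_query) — the convention of peak-set enrichment tools. The parameterization
requires n_bg ≥ n_query (draws cannot exceed the population; violating this
raises). If a motif is present in the query but absent from the background,
fold enrichment is +∞ and p is NA with an `undefined` flag rather than a
fabricated zero. Retention keeps fold > 0.5 (as printed in the protocol this
mirrors, although it admits depletion; configurable) and p < 0.05, ranked by
descending fold with ties broken by ascending p then id.

GC-matched backgrounds are sampled without replacement from quantile bins of
the query GC distribution (largest-remainder apportionment across bins,
seeded); pool peaks outside the query's GC range are ineligible.
`feasible_background_size` reports the largest attainable matched size, and
the pipeline falls back to the full non-DAP pool (logged) when matching
cannot supply at least n_query peaks. In the power/calibration experiments
the full pool is used directly: planted DAP GC is drawn from the same Beta
as the pool's, so the pool is GC-balanced by construction, and the larger
population keeps background motif counts away from the degenerate
small-count regime where a single chance hit yields extreme folds.

## TF–gene network

Spearman ρ = Pearson correlation of average ranks; two-sided p from
t = ρ√((n−2)/(1−ρ²)) with n−2 df (adequate at single-cell n; |ρ| = 1 gives
p = 0, constant input gives NA and the pair is dropped with a logged count).
Candidate pairs are (differentially expressed TFs) × (genes whose TSS window
is nonzero in ≥ 3 cells). Edges keep |ρ| > 0.3 and raw p < 0.05 — no
multiplicity adjustment, exactly as the retention rule is stated; a BH
option exists but defaults off and logs the deviation when enabled.
Correlations are computed on normalized values, but the rank-based statistic
makes any monotone normalization choice immaterial (property-tested). The
focal subnetwork is the top-k (default 20) targets by |ρ|, ties by ascending
p then id.

The pipeline pools neurons across conditions for the network by default
(more cells; the planted coupling acts cell-wise, so it holds in any
subset); `network_condition` restricts to a single timepoint.

## Prioritization

Motif names map to gene ids case-insensitively, heterodimer names splitting
on `::`. The per-timepoint Venn intersects enriched-motif TF genes with
upregulated DEGs (a flag admits all DEGs). Across timepoints, TFs present at
every supplied timepoint outrank partial-phase TFs; within a tier,
descending mean fold enrichment, then id — a deterministic total order.

## Problem sizes in tests and validation

The test suite and the acceptance script run on compact instances chosen to
make every statistical check well-powered while keeping a full run at a few
minutes on one CPU: ~300–800 cells, 150–500 genes, 60–2,000 peaks, and
20-seed batches for rate estimates. Monte-Carlo assertions use 3-SE (or
99 % binomial) bounds around their analytic expectations.
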