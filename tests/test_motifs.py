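"""Motif scanning, GC-matched backgrounds and hypergeometric enrichment."""

import math

import numpy as np
import pytest
import scipy.stats

from multigrn import (
    ConfigurationError,
    Peak,
    PositionFrequencyMatrix,
    SimConfig,
    gc_fraction,
    hypergeom_upper_tail,
    match_background_by_gc,
    motif_names_to_genes,
    pfm_to_pwm,
    rank_motifs,
    scan_motif,
    scan_peaks,
    simulate,
)
from multigrn.motifs import (
    MotifEnrichmentRecord,
    MotifOccurrenceMatrix,
    feasible_background_size,
    max_pwm_score,
)
from multigrn.motifs import test_motif_enrichment as motif_enrichment  # noqa: avoid pytest collection
from multigrn.simulate import generate_peak_sequences, generate_rna_counts


def brute_force_hypergeom_tail(k, n_query, K, N):
    """Oracle: sum the pmf C(K,i) C(N-K, n-i) / C(N, n) over i >= k."""
    total = math.comb(N, n_query)
    return sum(
        math.comb(K, i) * math.comb(N - K, n_query - i)
        for i in range(k, min(K, n_query) + 1)
    ) / total


class TestGcFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ACGT", 0.5), ("AAAA", 0.0), ("GCGC", 1.0), ("GNNN", 0.25), ("NNNN", 0.0)],
    )
    def test_examples(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_bad_characters_rejected(self):
        with pytest.raises(ConfigurationError):
            gc_fraction("ACGU")


class TestScanning:
    def test_uniform_pfm_scores_zero_bits(self):
        pfm = PositionFrequencyMatrix("U", "u", np.full((4, 4), 5.0))
        hits = scan_motif("ACGTACGTACGT", pfm, threshold_bits=0.0)
        assert len(hits) == 2 * (12 - 4 + 1)  # every window, both strands
        assert all(h[2] == pytest.approx(0.0) for h in hits)

    def test_consensus_sequence_maximal_hit(self):
        pfm = PositionFrequencyMatrix(
            "M", "m", np.array([[9, 0, 0], [0, 9, 0], [0, 0, 9], [0, 0, 0]]) + 0.5
        )
        seq = "TTTT" + "ACG" + "TTTT"
        hits = scan_motif(seq, pfm)
        assert any(h[0] == 4 and h[1] == "+" for h in hits)

    def test_sequence_shorter_than_motif_empty(self):
        pfm = PositionFrequencyMatrix("M", "m", np.ones((4, 6)))
        assert scan_motif("ACG", pfm) == []

    def test_strand_symmetry_with_reverse_complement_pfm(self, rng):
        counts = rng.integers(0, 10, size=(4, 5)).astype(float) + 0.5
        pfm = PositionFrequencyMatrix("M", "m", counts)
        rc = PositionFrequencyMatrix("Mrc", "mrc", counts[::-1, ::-1])
        seq = "".join(rng.choice(list("ACGT"), size=80))
        a = scan_motif(seq, pfm, threshold_bits=3.0)
        b = scan_motif(seq, rc, threshold_bits=3.0)
        flip = {"+": "-", "-": "+"}
        assert {(p, s) for p, s, _ in a} == {(p, flip[s]) for p, s, _ in b}

    def test_planted_peaks_all_detected(self):
        cfg = SimConfig(
            n_cells_per_subtype_per_condition=1, n_genes=50, n_peaks=200,
            n_dap_per_condition=30, n_markers_per_subtype=5, planted_targets_per_tf=5,
            motif_planting_rate_dap=1.0, motif_planting_rate_background=0.0,
            missing_gc_fraction=0.0, seed=17,
        )
        rna, cells, gt = generate_rna_counts(cfg)
        peaks, pfms = generate_peak_sequences(cfg, gt)
        occ = scan_peaks(peaks, [pfms[0]])
        planted = set(gt.motif_positive_peak_ids[pfms[0].motif_id])
        hit = dict(zip(occ.peak_ids, occ.indicators[:, 0]))
        assert all(hit[p] for p in planted)

    def test_pwm_max_score_positive_for_informative_motif(self):
        pfm = PositionFrequencyMatrix("M", "m", np.array([[20, 20], [0, 0], [0, 0], [0, 0]]) + 0.25)
        assert max_pwm_score(pfm_to_pwm(pfm)) > 3.0


class TestBackgroundMatching:
    def _peaks(self, gcs, prefix):
        return [
            Peak("chr1", 1000 * i, 1000 * i + 100, f"{prefix}{i}", gc_fraction=g)
            for i, g in enumerate(gcs)
        ]

    def test_matched_pool_histogram_close(self, rng):
        gcs = rng.beta(5, 5, 400)
        query = self._peaks(gcs[:100], "q")
        pool = self._peaks(gcs[100:], "p")
        bg = match_background_by_gc(query, pool, 100, seed=1)
        qh, edges = np.histogram([p.gc_fraction for p in query], bins=5)
        bh, _ = np.histogram([p.gc_fraction for p in bg], bins=edges)
        assert (np.abs(qh - bh) <= 2).all()

    def test_bimodal_pool_selects_matching_mode(self):
        query = self._peaks([0.7] * 20, "q")
        pool = self._peaks([0.3] * 30 + [0.7] * 30, "p")
        bg = match_background_by_gc(query, pool, 25, seed=0)
        assert all(p.gc_fraction == 0.7 for p in bg)

    def test_matched_beats_random_in_ks_distance(self, rng):
        gcs_q = rng.beta(6, 5, 150)  # GC-richer query
        gcs_p = rng.beta(5, 6, 1200)  # GC-poorer pool
        query = self._peaks(gcs_q, "q")
        pool = self._peaks(gcs_p, "p")
        n_bg = feasible_background_size(query, pool, 150)
        assert n_bg >= 50
        wins = 0
        for seed in range(20):
            bg = match_background_by_gc(query, pool, n_bg, seed=seed)
            rnd = np.random.default_rng(seed).choice(len(pool), n_bg, replace=False)
            ks_m = scipy.stats.ks_2samp(gcs_q, [p.gc_fraction for p in bg]).statistic
            ks_r = scipy.stats.ks_2samp(gcs_q, gcs_p[rnd]).statistic
            wins += ks_m <= ks_r
        assert wins >= 18

    def test_pool_overlap_rejected(self):
        q = self._peaks([0.5], "x")
        with pytest.raises(ConfigurationError, match="disjoint"):
            match_background_by_gc(q, q, 1)

    def test_insufficient_bin_named(self):
        query = self._peaks([0.2] * 5 + [0.8] * 5, "q")
        pool = self._peaks([0.2] * 20, "p")
        with pytest.raises(ConfigurationError, match="bin"):
            match_background_by_gc(query, pool, 10, n_bins=2, seed=0)


class TestEnrichment:
    def _occ(self, table):
        peak_ids = sorted(table)
        return MotifOccurrenceMatrix(
            peak_ids, ["M"], np.array([[table[p]] for p in peak_ids]), None
        )

    def _peaks(self, ids):
        return [Peak("chr1", 1000 * i, 1000 * i + 50, pid) for i, pid in enumerate(ids)]

    def test_fold_and_p_on_spec_sizes(self):
        q_ids = [f"q{i}" for i in range(10)]
        b_ids = [f"b{i}" for i in range(100)]
        table = {**{p: i < 4 for i, p in enumerate(q_ids)},
                 **{p: i < 10 for i, p in enumerate(b_ids)}}
        recs = motif_enrichment(self._peaks(q_ids), self._peaks(b_ids), self._occ(table))
        (r,) = recs
        assert r.fold_enrichment == pytest.approx(4.0)
        assert r.p == pytest.approx(0.008224876442577507, rel=1e-10)

    def test_identical_composition_fold_one(self):
        q_ids = [f"q{i}" for i in range(10)]
        b_ids = [f"b{i}" for i in range(20)]
        table = {**{p: i < 3 for i, p in enumerate(q_ids)},
                 **{p: i < 6 for i, p in enumerate(b_ids)}}
        (r,) = motif_enrichment(self._peaks(q_ids), self._peaks(b_ids), self._occ(table))
        assert r.fold_enrichment == pytest.approx(1.0)

    def test_absent_in_background_flagged(self):
        q_ids, b_ids = ["q0", "q1"], [f"b{i}" for i in range(10)]
        table = {**{p: True for p in q_ids}, **{p: False for p in b_ids}}
        (r,) = motif_enrichment(self._peaks(q_ids), self._peaks(b_ids), self._occ(table))
        assert r.fold_enrichment == float("inf")
        assert math.isnan(r.p) and r.undefined

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(50):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper_tail(k, n, K, N) == pytest.approx(
                brute_force_hypergeom_tail(k, n, K, N), rel=1e-10, abs=1e-300
            )

    def test_query_larger_than_background_rejected(self):
        with pytest.raises(ConfigurationError, match="population"):
            hypergeom_upper_tail(3, 50, 5, 20)

    def test_order_invariance(self, rng):
        ids = [f"p{i}" for i in range(30)]
        flags = rng.random(30) < 0.4
        occ = MotifOccurrenceMatrix(ids, ["M"], flags[:, None], None)
        peaks = self._peaks(ids)
        q, b = peaks[:10], peaks[10:]
        (r1,) = motif_enrichment(q, b, occ)
        (r2,) = motif_enrichment(q[::-1], b[::-1], occ)
        assert (r1.fold_enrichment, r1.p) == (r2.fold_enrichment, r2.p)


class TestRankMotifs:
    def _rec(self, mid, fold, p):
        return MotifEnrichmentRecord(mid, mid, 1, 10, 1, 100, fold, p)

    def test_threshold_filtering(self):
        recs = [self._rec("A", 3.0, 0.01), self._rec("B", 0.4, 0.001), self._rec("C", 2.0, 0.2)]
        assert [r.motif_id for r in rank_motifs(recs)] == ["A"]

    def test_empty_input(self):
        assert rank_motifs([]) == []

    def test_tie_broken_by_p_then_id(self):
        recs = [self._rec("B", 2.0, 0.01), self._rec("A", 2.0, 0.001),
                self._rec("C", 2.0, 0.001)]
        assert [r.motif_id for r in rank_motifs(recs)] == ["A", "C", "B"]

    def test_descending_fold(self):
        recs = [self._rec("A", 1.5, 0.01), self._rec("B", 4.0, 0.04)]
        assert [r.motif_id for r in rank_motifs(recs)] == ["B", "A"]


class TestNameMapping:
    def test_case_insensitive_and_heterodimer_split(self):
        genes = ["Creb5", "Mafb", "Sox6"]
        m = motif_names_to_genes(["CREB5", "MAFB::SOX6", "Pax2"], genes)
        assert m["CREB5"] == ["Creb5"]
        assert m["MAFB::SOX6"] == ["Mafb", "Sox6"]
        assert m["Pax2"] == []
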