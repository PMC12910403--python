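"""Wilcoxon differential testing, BH adjustment and the paper-style filters."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from multigrn import (
    ConfigurationError,
    CountMatrix,
    EmptyResultError,
    Peak,
    SimConfig,
    bh_adjust,
    exclude_missing_gc,
    find_differential_features,
    find_differential_tfs,
    lognormalize_rna,
    make_cell_table,
    simulate,
    tfidf_normalize_atac,
    wilcoxon_rank_sum,
)
from multigrn.diff import DifferentialFeatureResult, _wilcoxon_matrix


def exact_wilcoxon_p(x, y):
    """Independent oracle: enumerate all group assignments of the pooled
    sample; two-sided p = P(|U - mu| >= |u_obs - mu|)."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    hits = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxon:
    def test_extreme_separation_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)  # 2/20 assignments as extreme

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 5], [1, 2, 2, 5])
        assert p == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 6))
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_wilcoxon_p(x, y), abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=25)
        ux, px = wilcoxon_rank_sum(x, y)
        uy, py = wilcoxon_rank_sum(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))
        assert px == pytest.approx(py)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyResultError):
            wilcoxon_rank_sum([], [1.0])

    def test_type_i_error_rate(self, rng):
        reps = 1000
        x = rng.normal(size=(30, reps))
        y = rng.normal(size=(30, reps))
        p = _wilcoxon_matrix(x, y)
        rate = (p < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_matrix_path_matches_scalar(self, rng):
        x = rng.poisson(1.0, size=(25, 10)).astype(float)
        y = rng.poisson(1.2, size=(30, 10)).astype(float)
        pm = _wilcoxon_matrix(x, y)
        for j in range(10):
            _, pj = wilcoxon_rank_sum(x[:, j], y[:, j])
            assert pm[j] == pytest.approx(pj, abs=1e-12)

    def test_asymptotic_matches_scipy(self, rng):
        x = rng.poisson(1.0, size=40).astype(float)
        y = rng.poisson(1.5, size=35).astype(float)
        _, p = wilcoxon_rank_sum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(size=50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariance(self, pvals, pyrandom):
        perm = list(range(len(pvals)))
        pyrandom.shuffle(perm)
        direct = bh_adjust(pvals)
        permuted = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose([permuted[perm.index(i)] for i in range(len(pvals))], direct)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.5])


def _two_group_matrix(x, y, modality="ATAC_PEAK"):
    dense = np.vstack([x, y])
    n = dense.shape[0]
    cm = CountMatrix(
        sp.csr_matrix(dense), [f"c{i}" for i in range(n)],
        [f"f{j}" for j in range(dense.shape[1])], modality, normalized=True,
    )
    cond = ["7dpi"] * x.shape[0] + ["uninjured"] * y.shape[0]
    cells = make_cell_table(cm.cell_ids, ["Neurons"] * n, ["s0"] * n, cond)
    return cm, cells


class TestFindDifferentialFeatures:
    def test_low_detection_feature_excluded_before_testing(self, rng):
        n = 40
        x = np.zeros((n, 2))
        y = np.zeros((n, 2))
        # feature 0: nonzero in 10% of cells of both groups but hugely different
        x[:4, 0] = 100.0
        y[:4, 0] = 0.001
        # feature 1: well-detected control
        x[:, 1] = rng.poisson(3, n) + 1
        y[:, 1] = rng.poisson(3, n) + 1
        cm, cells = _two_group_matrix(x, y)
        res = find_differential_features(cm, cells, "7dpi", min_pct=0.20, return_all=True)
        assert {r.feature_id for r in res} == {"f1"}

    def test_planted_daps_recovered_up(self):
        cfg = SimConfig(
            n_cells_per_subtype_per_condition=50,  # 200 cells per condition
            n_genes=100, n_peaks=500, n_dap_per_condition=50, dap_fold=4.0,
            n_markers_per_subtype=5, planted_targets_per_tf=5, seed=8,
        )
        sim = simulate(cfg)
        norm = tfidf_normalize_atac(sim.atac_peaks)
        res = find_differential_features(norm, sim.cells, "7dpi")
        planted = set(sim.truth.planted_dap_ids["7dpi"])
        found_up = {r.feature_id for r in res if r.direction == "up"}
        assert len(planted & found_up) / len(planted) >= 0.9

    def test_absent_condition_named_in_error(self, rng):
        cm, cells = _two_group_matrix(rng.poisson(1, (5, 3)), rng.poisson(1, (5, 3)))
        with pytest.raises(EmptyResultError, match="14dpi"):
            find_differential_features(cm, cells, "14dpi")

    def test_filter_then_test_then_adjust_order_pinned(self, rng):
        """BH runs on the post-filter feature set: dropping a feature after
        adjustment would leave different p_adj than filtering first."""
        x = rng.poisson(2.0, size=(30, 20)).astype(float) + 1
        y = rng.poisson(1.0, size=(30, 20)).astype(float) + 1
        x[:, 5] = 0
        x[:28, 5] = 0  # feature 5 detected in <20% of either group
        y[:, 5] = 0
        cm, cells = _two_group_matrix(x, y)
        res = find_differential_features(cm, cells, "7dpi", return_all=True)
        assert len(res) == 19
        pv = [r.p for r in res]
        np.testing.assert_allclose([r.p_adj for r in res], bh_adjust(pv), rtol=1e-12)


class TestExcludeMissingGc:
    def _daps(self, ids):
        return [
            DifferentialFeatureResult(i, 1.0, 0.5, 0.3, 0.01, 0.02, "up") for i in ids
        ]

    def test_no_missing_identity(self):
        peaks = [Peak("chr1", i * 10, i * 10 + 5, f"p{i}", gc_fraction=0.5) for i in range(4)]
        daps = self._daps([p.peak_id for p in peaks])
        assert exclude_missing_gc(daps, peaks) == daps

    def test_missing_removed(self):
        peaks = [
            Peak("chr1", i * 10, i * 10 + 5, f"p{i}", gc_fraction=None if i < 3 else 0.5)
            for i in range(10)
        ]
        out = exclude_missing_gc(self._daps([p.peak_id for p in peaks]), peaks)
        assert len(out) == 7

    def test_simulated_missing_rate_within_binomial_bounds(self, small_sim, small_cfg):
        daps = self._daps([p.peak_id for p in small_sim.peaks])
        out = exclude_missing_gc(daps, small_sim.peaks)
        removed = len(daps) - len(out)
        lo, hi = scipy.stats.binom.ppf(
            [0.005, 0.995], small_cfg.n_peaks, small_cfg.missing_gc_fraction
        )
        assert lo <= removed <= hi + 1  # rounding of the planted missing count


class TestFindDifferentialTfs:
    def test_focal_tf_found_at_acute_phase(self, small_sim):
        norm = lognormalize_rna(small_sim.rna)
        tf_names = ["CREB5", "gene001", "gene002"]
        res = find_differential_tfs(norm, small_sim.cells, tf_names, "7dpi")
        assert small_sim.truth.focal_tf_id in {r.feature_id for r in res}
        by_id = {r.feature_id: r for r in res}
        assert by_id[small_sim.truth.focal_tf_id].direction == "up"

    def test_disjoint_tf_set_rejected(self, small_sim):
        norm = lognormalize_rna(small_sim.rna)
        with pytest.raises(EmptyResultError):
            find_differential_tfs(norm, small_sim.cells, ["NoSuchGene"], "7dpi")

    def test_effect_free_sim_mostly_empty(self):
        empty = 0
        for seed in range(10):
            cfg = SimConfig(
                n_cells_per_subtype_per_condition=20, n_genes=120, n_peaks=100,
                n_dap_per_condition=10, n_markers_per_subtype=5, planted_targets_per_tf=5,
                marker_fold=1.0, dap_fold=1.0, focal_tf_fold=1.0, coupling_beta=0.0,
                seed=100 + seed,
            )
            sim = simulate(cfg)
            norm = lognormalize_rna(sim.rna)
            res = find_differential_tfs(
                norm, sim.cells, ["Creb5", "gene001", "gene002", "gene003"], "7dpi"
            )
            empty += not res
        assert empty >= 9
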