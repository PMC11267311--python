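"""Differential expression: rank-sum oracles, BH, filters, antisymmetry."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats

from gbotools import deg
from gbotools.matrix import CountMatrix


def brute_force_ranksum_p(values_a, values_b):
    """Exhaustive two-sided rank-sum p over all group assignments.

    Enumerates every size-|A| subset of the pooled observations (midranks
    for ties) and reports P(|W - mu| >= |w_obs - mu|) under the uniform
    permutation null.
    """
    pooled = np.concatenate([values_a, values_b])
    ranks = scipy.stats.rankdata(pooled)
    n_a = len(values_a)
    mu = n_a * (len(pooled) + 1) / 2.0
    dev = abs(ranks[:n_a].sum() - mu)
    sums = np.array(
        [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n_a)]
    )
    return np.sum(np.abs(sums - mu) >= dev - 1e-9) / comb(len(pooled), n_a)


def _matrix_from_dense(dense):
    dense = np.asarray(dense)
    genes = np.array([f"g{i}" for i in range(dense.shape[0])], dtype=object)
    bcs = np.array([f"BC{i}" for i in range(dense.shape[1])], dtype=object)
    return CountMatrix(sp.csr_matrix(dense), genes, bcs)


class TestWilcoxon:
    def test_identical_groups_null_result(self):
        block = np.array([[3, 0, 5], [1, 1, 2], [0, 0, 0]])
        mat = _matrix_from_dense(np.hstack([block, block]))
        out = deg.wilcoxon_deg(mat, np.arange(3), np.arange(3, 6))
        assert np.allclose(out["log2fc"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_pseudocount_forces_log2fc(self):
        # normalized meanA=3, meanB=0 -> log2((3+1)/(0+1)) = 2
        mat = _matrix_from_dense([[3, 3, 0, 0], [7, 7, 10, 10]])
        # cell totals 10 -> scale 1e4 gives x1000; construct so gene0
        # normalized means are 3 and 0 on a 1e4/1e4-total scale
        norm = deg.lognormalize(mat)
        a = np.expm1(norm[0, :2]).mean()
        b = np.expm1(norm[0, 2:]).mean()
        out = deg.wilcoxon_deg(mat, np.arange(2), np.arange(2, 4))
        assert out["log2fc"][0] == pytest.approx(np.log2((a + 1) / (b + 1)))
        assert out["log2fc"][0] == pytest.approx(np.log2(3001.0), rel=1e-6)

    @pytest.mark.parametrize("n_a,n_b", [(2, 3), (4, 4), (5, 3), (8, 8), (6, 8)])
    def test_exact_path_equals_exhaustive_enumeration(self, n_a, n_b):
        rng = np.random.default_rng(n_a * 10 + n_b)
        dense = rng.poisson(2.0, size=(6, n_a + n_b))
        dense[:, 0] += 1  # avoid zero-total cells
        dense[0] = 0
        dense[0, 0] = 1
        mat = _matrix_from_dense(dense + (dense.sum(0) == 0))
        out = deg.wilcoxon_deg(mat, np.arange(n_a), np.arange(n_a, n_a + n_b))
        norm = deg.lognormalize(mat)
        for g in range(6):
            expected = brute_force_ranksum_p(norm[g, :n_a], norm[g, n_a:])
            assert out["p"][g] == pytest.approx(expected, abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # tie-free fixtures: with heavy ties at these sizes the rank-sum
        # lattice is too coarse for any normal approximation (the exact
        # path handles those); continuous data is the approximation's remit
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(100):
            n_a = int(rng.integers(5, 9))
            n_b = int(rng.integers(5, 9))
            a = rng.normal(0.0, 1.0, n_a)
            b = rng.normal(0.8, 1.0, n_b)
            pooled = np.concatenate([a, b])
            ranks = scipy.stats.rankdata(pooled)
            p_norm = deg._normal_ranksum_p(
                np.array([ranks[:n_a].sum()]), n_a, n_b, np.array([0.0])
            )[0]
            p_exact = brute_force_ranksum_p(a, b)
            worst = max(worst, abs(p_norm - p_exact))
        assert worst < 0.02

    def test_antisymmetry_under_group_swap(self, planted_design_matrix):
        mat, _ = planted_design_matrix
        ia, ib = deg.groups_from_labels(mat.samples, "PFC_4MPT", "HIP_4MPT")
        ia, ib = ia[:30], ib[:30]
        fwd = deg.wilcoxon_deg(mat, ia, ib)
        rev = deg.wilcoxon_deg(mat, ib, ia)
        assert np.allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        assert np.allclose(fwd["p"], rev["p"], atol=1e-12)
        assert np.allclose(fwd["pct1"], rev["pct2"])

    def test_overlapping_groups_rejected(self, random_count_matrix):
        with pytest.raises(ValueError, match="overlap"):
            deg.wilcoxon_deg(random_count_matrix, np.arange(5), np.arange(4, 9))

    def test_null_p_distribution_calibrated(self):
        rng = np.random.default_rng(7)
        dense = rng.poisson(3.0, size=(400, 60)) + 1
        mat = _matrix_from_dense(dense)
        out = deg.wilcoxon_deg(mat, np.arange(30), np.arange(30, 60))
        frac = (out["p"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.03)
        # BH under the global null controls FWER at ~alpha, so discoveries
        # are rare but a stray sub-Bonferroni p occurs on ~5% of draws
        assert (out["p_adj"] < 0.05).sum() <= 2


class TestBH:
    def test_single_p_unchanged(self):
        assert deg.bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        out = deg.bh_adjust(np.full(10, 0.2))
        assert np.allclose(out, 0.2)

    def test_matches_direct_stepup_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(size=100)
            out = deg.bh_adjust(p)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            # direct definition: min over k >= rank of p(k) * m / k
            sorted_p = p[order]
            adj = np.minimum.accumulate((sorted_p * m / np.arange(1, m + 1))[::-1])[::-1]
            expected[order] = np.minimum(adj, 1)
            assert np.allclose(out, expected, atol=1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=250)
        ours = deg.bh_adjust(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_never_decreases_and_bounded(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        out = deg.bh_adjust(p)
        assert np.all(out >= p - 1e-15)
        assert np.all(out <= 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            deg.bh_adjust(np.array([0.1, np.nan]))


class TestFilter:
    def _records(self):
        return pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "log2fc": [0.1, 0.5, -0.6],
                "p": [0.001, 0.001, 0.2],
                "p_adj": [0.01, 0.01, 0.5],
                "pct1": [0.5, 0.5, 0.9],
                "pct2": [0.2, 0.05, 0.9],
            }
        )

    def test_vacuous_thresholds_pass_everything(self):
        out = deg.filter_deg(
            self._records(), deg.DEGThresholds(alpha=1.0, min_pct=0.0, min_abs_log2fc=0.0)
        )
        assert out["passes"].all()

    def test_fold_change_criterion_blocks_small_effects(self):
        out = deg.filter_deg(self._records())
        assert not out.set_index("gene")["passes"]["a"]  # |lfc|=0.1 < 0.25
        assert out.set_index("gene")["passes"]["b"]
        assert not out.set_index("gene")["passes"]["c"]  # p_adj too big

    def test_pct_mode_min_is_stricter(self):
        strict = deg.filter_deg(self._records(), deg.DEGThresholds(pct_mode="min"))
        assert not strict.set_index("gene")["passes"]["b"]  # min pct 0.05 < 0.1
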