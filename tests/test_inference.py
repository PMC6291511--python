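"""Permutation testing, FDR correction, chi-square and correlation checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from plimst import (
    chi_square_2x2,
    compare_groups,
    compare_incident_links,
    fdr_bh,
    inclusion_frequency_test,
    pearson_correlation,
    permutation_test,
    welch_t_test,
)
from plimst.connectivity import ConnectivityMatrix
from plimst.tree import SpanningTree
from conftest import path_tree, star_tree


class TestPermutationTest:
    def test_identical_constant_groups(self):
        res = permutation_test([5, 5, 5], [5, 5, 5])
        assert res.p_raw == 1.0
        assert res.observed_diff == 0.0

    def test_exhaustive_two_vs_two(self):
        # all C(4,2)=6 label splits; |diff|=9 attained by 2 of them
        res = permutation_test([1, 2], [10, 11])
        assert res.exhaustive
        assert res.p_raw == pytest.approx(1 / 3)
        assert res.observed_diff == pytest.approx(-9.0)

    def test_seeded_determinism(self, rng):
        a, b = rng.standard_normal(20), rng.standard_normal(20)
        r1 = permutation_test(a, b, n_perm=500, seed=42)
        r2 = permutation_test(a, b, n_perm=500, seed=42)
        assert r1.p_raw == r2.p_raw

    def test_group_swap_invariance(self, rng):
        a, b = rng.standard_normal(16), rng.standard_normal(16)
        r1 = permutation_test(a, b, n_perm=400, seed=7)
        r2 = permutation_test(b, a, n_perm=400, seed=7)
        assert r1.p_raw == r2.p_raw
        assert r1.observed_diff == -r2.observed_diff

    def test_monte_carlo_close_to_exhaustive(self, rng):
        # total size 10 -> exhaustive C(10,5)=252; compare a forced MC run
        from plimst import inference

        a, b = rng.standard_normal(5), rng.standard_normal(5) + 1.0
        exact = permutation_test(a, b).p_raw
        old = inference.EXHAUSTIVE_LIMIT
        inference.EXHAUSTIVE_LIMIT = 1
        try:
            mc = permutation_test(a, b, n_perm=10_000, seed=1).p_raw
        finally:
            inference.EXHAUSTIVE_LIMIT = old
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) < 3 * se + 2e-4

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])


class TestFdrBH:
    def test_hand_computed_example(self):
        assert np.allclose(fdr_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert fdr_bh([0.2]) == pytest.approx([0.2])

    def test_empty_list(self):
        assert fdr_bh([]).size == 0

    def test_ties_adjusted_to_common_value(self):
        assert np.allclose(fdr_bh([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    @given(st.integers(0, 2**32 - 1), st.integers(1, 60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_dominates_raw(self, seed, m):
        p = np.random.default_rng(seed).uniform(1e-9, 1.0, m)
        adj = fdr_bh(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adj, ref, atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


class TestChiSquare:
    def test_two_by_two_value(self):
        # Pearson chi-square, no continuity correction, for [[10,6],[3,13]]
        chi2, p = chi_square_2x2(np.array([[10, 6], [3, 13]]))
        assert chi2 == pytest.approx(6.3482, abs=1e-4)
        assert p < 0.05

    def test_identical_patterns_give_zero(self):
        chi2, p = chi_square_2x2(np.array([[8, 8], [8, 8]]))
        assert chi2 == 0.0 and p == 1.0

    def test_degenerate_margin_convention(self):
        chi2, p = chi_square_2x2(np.array([[16, 16], [0, 0]]))
        assert (chi2, p) == (0.0, 1.0)


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-6, 8)
        b = 1 + rng.normal(0, 1e-6, 8)
        _, p = welch_t_test(a, b)
        assert p < 1e-10

    def test_both_constant_equal(self):
        assert welch_t_test([2, 2], [2, 2]) == (0.0, 1.0)


class TestPearson:
    def test_exact_linearity(self):
        res = pearson_correlation([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)

    def test_hand_computed_half(self):
        res = pearson_correlation([1, 2, 3], [2, 1, 3])
        assert res.r == pytest.approx(0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 2], [3, 4])


def _metric_table(rng, n_per_group=6, nodes=("n0", "n1"), band="theta"):
    rows = []
    for g, off in (("A", 0.0), ("B", 0.3)):
        for s in range(n_per_group):
            sid = f"{g}{s}"
            for metric in ("leaf_fraction", "tree_hierarchy", "degree_divergence"):
                rows.append(dict(subject=sid, group=g, band=band, metric=metric,
                                 node="global", value=rng.normal(off)))
            for node in nodes:
                rows.append(dict(subject=sid, group=g, band=band,
                                 metric="degree", node=node, value=rng.normal(off)))
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_global_scope_three_results(self, rng):
        table = _metric_table(rng)
        res = compare_groups(table, "global", "theta", n_perm=200, seed=0)
        assert len(res) == 3
        assert {r.metric_id for r in res} == {
            "leaf_fraction", "tree_hierarchy", "degree_divergence"
        }
        for r in res:
            assert r.p_fdr >= r.p_raw

    def test_nodal_scope_one_result_per_node(self, rng):
        table = _metric_table(rng)
        res = compare_groups(table, "nodal", "theta", "degree", n_perm=200, seed=0)
        assert len(res) == 2
        assert sorted(r.metric_id for r in res) == ["degree:n0", "degree:n1"]

    def test_incomplete_table_rejected(self, rng):
        table = _metric_table(rng)
        table = table.drop(table[(table.subject == "A0") & (table.node == "n0")].index)
        with pytest.raises(ValueError, match="incomplete"):
            compare_groups(table, "nodal", "theta", "degree", n_perm=50, seed=0)


class TestIncidentLinks:
    @staticmethod
    def _mats(rng, n_sub, bump=0.0):
        mats = []
        for _ in range(n_sub):
            v = rng.uniform(0.1, 0.4, (4, 4))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 0)
            v[0, 1] += bump
            v[1, 0] += bump
            mats.append(ConnectivityMatrix(np.clip(v, 0, 1)))
        return mats

    def test_one_test_per_incident_link(self, rng):
        a = self._mats(rng, 5)
        b = self._mats(rng, 5)
        res = compare_incident_links(a, b, "ROI00", n_perm=100, seed=0)
        assert len(res) == 3  # 4 ROIs -> 3 incident links

    def test_strengthened_link_detected(self, rng):
        a = self._mats(rng, 10)
        b = self._mats(rng, 10, bump=0.5)
        res = compare_incident_links(a, b, "ROI00", n_perm=500, seed=0)
        assert res[0].metric_id == "pli:ROI00-ROI01"
        assert res[0].p_fdr < 0.05

    def test_unknown_node_rejected(self, rng):
        a = self._mats(rng, 3)
        with pytest.raises(ValueError, match="unknown"):
            compare_incident_links(a, a, "nope")


class TestInclusionFrequency:
    def test_identical_patterns_chi2_zero(self):
        trees = [path_tree(4) for _ in range(6)]
        res = inclusion_frequency_test(trees, [path_tree(4) for _ in range(6)], "ROI01")
        assert all(r.chi2 == 0.0 and r.p_raw == 1.0 for r in res)

    def test_always_included_link_degenerate(self):
        trees_a = [star_tree(4) for _ in range(5)]
        trees_b = [star_tree(4) for _ in range(5)]
        res = inclusion_frequency_test(trees_a, trees_b, "ROI00")
        assert all(r.p_raw == 1.0 for r in res)

    def test_divergent_patterns_detected(self):
        trees_a = [star_tree(6) for _ in range(12)]
        trees_b = [path_tree(6) for _ in range(12)]
        res = inclusion_frequency_test(trees_a, trees_b, "ROI00")
        # star center uses links 0-2..0-5 which the path never does
        sig = [r for r in res if r.p_fdr < 0.05]
        assert len(sig) >= 3

    def test_counts_sum_to_group_sizes(self):
        trees_a = [star_tree(5) for _ in range(7)]
        trees_b = [path_tree(5) for _ in range(9)]
        res = inclusion_frequency_test(trees_a, trees_b, "ROI02")
        for r in res:
            assert r.counts[:, 0].sum() == 7
            assert r.counts[:, 1].sum() == 9
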