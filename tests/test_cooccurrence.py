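import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncycnet import EdgeCriterion, adjust_pvalues_bh, build_network, spearman_matrix
from conftest import make_matrix
from oracles import bh_stepup, spearman_brute


class TestSpearmanMatrix:
    def test_perfect_monotone(self):
        m = make_matrix(np.array([[1, 2], [2, 4], [3, 6], [4, 8]]))
        corr = spearman_matrix(m, min_pairs=4)
        assert corr.rho.loc["a1", "a2"] == pytest.approx(1.0)

    def test_perfect_antitone(self):
        m = make_matrix(np.array([[1, 8], [2, 6], [3, 4], [4, 2]]))
        corr = spearman_matrix(m, min_pairs=4)
        assert corr.rho.loc["a1", "a2"] == pytest.approx(-1.0)

    def test_rank_difference_formula(self):
        # d = (0, -1, 1, 0, 1): rho = 1 - 6*4 / (5*24) = 0.8
        m = make_matrix(np.array([[1, 1], [2, 3], [3, 2], [4, 5], [5, 4]]))
        corr = spearman_matrix(m, min_pairs=4)
        assert corr.rho.loc["a1", "a2"] == pytest.approx(0.8)

    def test_pairwise_complete_counts_and_min_pairs_mask(self):
        vals = np.column_stack([np.arange(12.0), np.arange(12.0) * 2, np.arange(12.0) ** 2])
        vals[:9, 2] = np.nan  # only 3 complete pairs against a3
        m = make_matrix(vals)
        corr = spearman_matrix(m, min_pairs=10)
        assert corr.n_pairs.loc["a1", "a3"] == 3
        assert np.isnan(corr.rho.loc["a1", "a3"])
        assert np.isnan(corr.p_adj.loc["a1", "a3"])
        assert corr.rho.loc["a1", "a2"] == pytest.approx(1.0)

    def test_constant_column_masked_not_error(self):
        vals = np.column_stack([np.arange(12.0), np.full(12, 6.0)])
        m = make_matrix(vals)
        corr = spearman_matrix(m, min_pairs=10)
        assert np.isnan(corr.rho.loc["a1", "a2"])

    def test_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(42)
        m = make_matrix(rng.normal(6, 0.5, (15, 6)))
        corr = spearman_matrix(m, min_pairs=10)
        for mat in (corr.rho, corr.p_raw, corr.p_adj, corr.n_pairs):
            np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr.rho), 1.0)

    def test_p_adj_dominates_p_raw(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(6, 0.5, (20, 8)))
        corr = spearman_matrix(m, min_pairs=10)
        tri = np.triu_indices(8, k=1)
        raw = corr.p_raw.to_numpy()[tri]
        adj = corr.p_adj.to_numpy()[tri]
        assert np.all(adj >= raw - 1e-12)

    def test_matches_midrank_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 5, 15).astype(float)  # forces ties
        y = rng.integers(0, 5, 15).astype(float)
        m = make_matrix(np.column_stack([x, y]))
        corr = spearman_matrix(m, min_pairs=10)
        assert corr.rho.loc["a1", "a2"] == pytest.approx(spearman_brute(list(x), list(y)))

    def test_long_export_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(6, 0.5, (15, 4)))
        corr = spearman_matrix(m, min_pairs=10)
        corr.to_tsv(tmp_path / "corr.tsv")
        back = pd.read_csv(tmp_path / "corr.tsv", sep="\t")
        assert len(back) == 6
        assert set(back.columns) == {"assay_a", "assay_b", "rho", "p_raw", "p_adj", "n_pairs"}


class TestBenjaminiHochberg:
    def test_step_up_with_cumulative_minimum(self):
        np.testing.assert_allclose(adjust_pvalues_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_value_identity(self):
        np.testing.assert_allclose(adjust_pvalues_bh([0.3]), [0.3])

    def test_two_value_example(self):
        np.testing.assert_allclose(adjust_pvalues_bh([0.005, 0.5]), [0.01, 0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues_bh([0.5, 1.5])

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(adjust_pvalues_bh(pvals), bh_stepup(pvals), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_monotone_and_order_preserving(self, pvals):
        adj = adjust_pvalues_bh(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestBuildNetwork:
    def _corr(self, n=16, k=3, tweak=None):
        rng = np.random.default_rng(11)
        base = rng.normal(0, 1, n)
        cols = np.column_stack([base + rng.normal(0, s, n) for s in (0.1, 0.1, 5.0)[:k]])
        m = make_matrix(6 + 0.5 * cols)
        return spearman_matrix(m, min_pairs=10)

    def test_single_qualifying_pair(self):
        corr = self._corr(k=2)
        g = build_network(corr, EdgeCriterion())
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        d = g.edges["a1", "a2"]
        assert abs(d["rho"]) > 0.75 and d["p_adj"] < 0.01 and d["sign"] == 1

    def test_nothing_passes_gives_empty_network(self):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(6, 0.5, (20, 4)))
        g = build_network(spearman_matrix(m, min_pairs=10), EdgeCriterion())
        assert g.number_of_edges() == 0

    def test_joint_criterion_needs_both_thresholds(self):
        corr = self._corr(k=2)
        strict_alpha = EdgeCriterion(alpha=1e-30)
        assert build_network(corr, strict_alpha).number_of_edges() == 0
        strict_rho = EdgeCriterion(rho_min=0.999)
        assert build_network(corr, strict_rho).number_of_edges() == 0

    def test_negative_correlation_edge_with_absolute_criterion(self):
        x = np.arange(16.0)
        m = make_matrix(np.column_stack([x, -x]) + 20)
        g = build_network(spearman_matrix(m, min_pairs=10), EdgeCriterion(use_absolute=True))
        assert g.number_of_edges() == 1
        assert g.edges["a1", "a2"]["sign"] == -1
        g_pos = build_network(spearman_matrix(m, min_pairs=10), EdgeCriterion(use_absolute=False))
        assert g_pos.number_of_edges() == 0

    def test_signed_and_absolute_agree_without_negatives(self):
        corr = self._corr()
        g_abs = build_network(corr, EdgeCriterion(use_absolute=True))
        g_pos = build_network(corr, EdgeCriterion(use_absolute=False))
        assert set(g_abs.edges) == set(g_pos.edges)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        m_log = make_matrix(rng.normal(6, 0.5, (25, 5)))
        m_raw = m_log.to_copies_per_g()
        crit = EdgeCriterion(rho_min=0.3, alpha=0.3)
        g_log = build_network(spearman_matrix(m_log, min_pairs=10), crit)
        g_raw = build_network(spearman_matrix(m_raw, min_pairs=10), crit)
        assert set(map(frozenset, g_log.edges)) == set(map(frozenset, g_raw.edges))

    def test_provenance_recorded(self):
        corr = self._corr(k=2)
        g = build_network(corr, EdgeCriterion(), provenance={"location": "siteX", "timepoint": 1})
        assert g.graph["location"] == "siteX"
        assert g.graph["criterion"]["rho_min"] == 0.75
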