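"""Metagene, tertiles, contingency chi-squared, resampling null, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import synlet as sl
from synlet.expression_prep import ExpressionMatrix
from synlet.sl_metagene import NullDistribution, _tertile_codes


def bh_step_up(p):
    """Hand-coded Benjamini-Hochberg step-up (oracle)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def labels_from_table(table):
    """Expand a 3x3 count table into a pair of label vectors."""
    a, b = [], []
    for i in range(3):
        for j in range(3):
            a += [i] * table[i][j]
            b += [j] * table[i][j]
    return np.array(a), np.array(b)


class TestMetagene:
    def test_rank_one_recovers_factor_exactly(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal(40)
        w = rng.uniform(0.5, 2.0, 12)
        mg = sl.compute_metagene(np.outer(w, f), "rank1")
        assert abs(np.corrcoef(mg.scores, f)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert mg.explained_variance == pytest.approx(1.0, abs=1e-9)
        assert np.linalg.norm(mg.scores) == pytest.approx(1.0)

    def test_global_flip_changes_nothing_downstream(self):
        # flipping every entry can only flip the metagene's sign, which the
        # tertile chi-squared is exactly invariant to
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 30))
        a = sl.compute_metagene(x)
        b = sl.compute_metagene(-x)
        assert np.allclose(a.scores, b.scores) or np.allclose(a.scores, -b.scores)
        assert a.explained_variance == pytest.approx(b.explained_variance)
        anchor = sl.tertile_bin(rng.standard_normal(30))
        chi_a = sl.contingency_chi2(anchor, sl.tertile_bin(a.scores)).chi2
        chi_b = sl.contingency_chi2(anchor, sl.tertile_bin(b.scores)).chi2
        assert chi_a == pytest.approx(chi_b)

    def test_sign_convention_tracks_mean_member_expression(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            x = rng.standard_normal((8, 40))
            mg = sl.compute_metagene(x)
            assert float(mg.scores @ x.mean(axis=0)) >= 0

    def test_noisy_factor_recovery(self):
        rng = np.random.default_rng(2)
        f = rng.standard_normal(415)
        x = f[None, :] + rng.standard_normal((50, 415))  # loading 1, noise sd 1
        x = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        mg = sl.compute_metagene(x)
        assert abs(np.corrcoef(mg.scores, f)[0, 1]) > 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="non-constant"):
            sl.compute_metagene(np.ones((5, 20)))
        with pytest.raises(ValueError, match="9 samples"):
            sl.compute_metagene(np.random.default_rng(0).standard_normal((5, 5)))
        m = ExpressionMatrix(
            pd.DataFrame(np.random.default_rng(0).standard_normal((3, 12))),
            stage="log_expression",
        )
        with pytest.raises(ValueError, match="standardized"):
            sl.compute_metagene(m)


class TestTertiles:
    def test_nine_values(self):
        labels = sl.tertile_bin(np.arange(1, 10))
        assert labels.tolist() == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3

    def test_floor_rule_sizes(self):
        labels = sl.tertile_bin(np.random.default_rng(0).permutation(10))
        counts = pd.Series(labels).value_counts()
        assert counts["low"] == 3 and counts["mid"] == 4 and counts["high"] == 3

    def test_ties_resolved_by_input_order(self, caplog):
        with caplog.at_level("WARNING"):
            labels = sl.tertile_bin(np.zeros(9))
        assert labels.tolist() == ["low"] * 3 + ["mid"] * 3 + ["high"] * 3
        assert "equal" in caplog.text

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sl.tertile_bin(np.arange(8))


class TestContingencyChi2:
    def test_perfect_agreement_n9(self):
        a = sl.tertile_bin(np.arange(9))
        res = sl.contingency_chi2(a, a)
        assert np.array_equal(res.table, np.diag([3, 3, 3]))
        assert res.chi2 == pytest.approx(18.0)
        assert res.df == 4

    def test_exact_independence_is_zero(self):
        a = np.repeat([0, 1, 2], 3)
        b = np.tile([0, 1, 2], 3)
        assert sl.contingency_chi2(a, b).chi2 == pytest.approx(0.0)

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 3, 60)
        b = rng.integers(0, 3, 60)
        base = sl.contingency_chi2(a, b).chi2
        assert sl.contingency_chi2(a, 2 - b).chi2 == pytest.approx(base)
        assert sl.contingency_chi2(2 - a, b).chi2 == pytest.approx(base)

    def test_degenerate_margin_rejected(self):
        a = np.repeat([0, 1], 6)  # only two categories
        b = np.tile([0, 1, 2], 4)
        with pytest.raises(ValueError):
            sl.contingency_chi2(a, b)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            table = rng.integers(1, 30, (3, 3))
            a, b = labels_from_table(table.tolist())
            ours = sl.contingency_chi2(a, b).chi2
            ref = sps.chi2_contingency(table, correction=False).statistic
            assert ours == pytest.approx(ref, abs=1e-9)


class TestNullAndEmpiricalP:
    @staticmethod
    def _noise_matrix(n_genes=400, n_samples=120, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)),
            index=[f"g{i}" for i in range(n_genes)],
        )
        m = ExpressionMatrix(df, stage="log_expression")
        return sl.standardize_genes(m)

    def test_null_is_deterministic(self):
        std = self._noise_matrix()
        anchor = sl.tertile_bin(np.arange(std.n_samples))
        n1 = sl.build_null(10, std, anchor, n_iter=100, seed=42)
        n2 = sl.build_null(10, std, anchor, n_iter=100, seed=42)
        assert np.array_equal(n1.stats, n2.stats)

    def test_null_mean_matches_observed_random_sets(self):
        # exchangeability: resampled stats and observed stats of random
        # disjoint gene sets estimate the same distribution
        std = self._noise_matrix(seed=5)
        rng = np.random.default_rng(6)
        anchor_vals = rng.standard_normal(std.n_samples)
        anchor = sl.tertile_bin(anchor_vals)
        null = sl.build_null(20, std, anchor, n_iter=1500, seed=7)
        genes = std.values.index.to_numpy()
        rng.shuffle(genes)
        observed = []
        for i in range(0, 400, 20):
            mg = sl.compute_metagene(std.values.loc[genes[i : i + 20]])
            observed.append(sl.contingency_chi2(anchor, sl.tertile_bin(mg.scores)).chi2)
        se = np.sqrt(null.stats.var() / null.n_iter + np.var(observed) / len(observed))
        assert abs(null.stats.mean() - np.mean(observed)) < 3 * se

    def test_anchor_linked_correlation_inflates_null_beyond_chi2_df4(self):
        # cohort-wide correlation with the anchor (e.g. an epithelial
        # programme co-expressed with it) is exactly what the resampling
        # null must absorb: random gene sets pick it up, pushing the null
        # far above the nominal df=4 distribution
        rng = np.random.default_rng(8)
        anchor_vals = rng.standard_normal(120)
        x = rng.standard_normal((300, 120))
        x[:150] += 0.8 * anchor_vals[None, :]
        m = ExpressionMatrix(pd.DataFrame(x, index=[f"g{i}" for i in range(300)]), stage="log_expression")
        std = sl.standardize_genes(m)
        anchor = sl.tertile_bin(anchor_vals)
        null = sl.build_null(20, std, anchor, n_iter=800, seed=9)
        assert np.median(null.stats) > sps.chi2(4).median()
        assert np.quantile(null.stats, 0.95) > sps.chi2(4).ppf(0.95)

    def test_exceeds_universe_rejected(self):
        std = self._noise_matrix(n_genes=30)
        anchor = sl.tertile_bin(np.arange(std.n_samples))
        with pytest.raises(ValueError, match="exceeds"):
            sl.build_null(31, std, anchor, n_iter=10, seed=0)

    def test_empirical_p_counting_rules(self):
        null = NullDistribution(k=5, n_iter=499, stats=np.sort(np.arange(499.0)), seed=0)
        assert sl.empirical_p(-1.0, null) == pytest.approx(1.0)
        assert sl.empirical_p(1e9, null) == pytest.approx(1 / 500)
        assert sl.empirical_p(1e9, null, correction="raw") == 0.0
        med = float(np.median(null.stats))
        assert sl.empirical_p(med, null, correction="raw") == pytest.approx(0.5, abs=0.01)


class TestAdjustFdr:
    def test_single_p_unchanged(self):
        assert sl.adjust_fdr([0.07])[0] == pytest.approx(0.07)

    def test_hand_worked_example(self):
        assert np.allclose(sl.adjust_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sl.adjust_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=200)
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(sl.adjust_fdr(p), bh_step_up(p), atol=1e-12)


class TestOverlapAndLayout:
    def test_overlap_matrix(self):
        sets = sl.GeneSetCollection(
            {"s1": ("A", "B", "C"), "s2": ("B", "C", "D"), "s3": ("X", "Y")}
        )
        counts, jaccard = sl.pathway_overlap(sets)
        assert counts.loc["s1", "s1"] == 3
        assert counts.loc["s1", "s2"] == 2
        assert jaccard.loc["s1", "s2"] == pytest.approx(0.5)
        assert counts.loc["s1", "s3"] == 0
        assert jaccard.loc["s3", "s3"] == 1.0

    @staticmethod
    def _layout_matrix():
        rng = np.random.default_rng(10)
        anchor = rng.standard_normal(20)
        rows = {
            "CDH1": anchor,
            "g1": rng.standard_normal(20),
            "g3": rng.standard_normal(20) * 5,
        }
        rows["g2"] = rows["g1"] + rng.standard_normal(20) * 0.01  # near-duplicate of g1
        df = pd.DataFrame(rows).T
        df.columns = [f"t{i}" for i in range(20)]
        return ExpressionMatrix(df, stage="log_expression"), anchor

    def test_close_rows_merge_first_and_cluster_together(self):
        m, _ = self._layout_matrix()
        layout = sl.heatmap_layout(m, ["g1", "g2", "g3"], "CDH1")
        order = layout.gene_order
        assert abs(order.index("g1") - order.index("g2")) == 1
        assert layout.clusters["g1"] == layout.clusters["g2"]

    def test_sample_order_follows_anchor(self):
        m, anchor = self._layout_matrix()
        layout = sl.heatmap_layout(m, ["g1", "g2", "g3"], "CDH1")
        expected = [f"t{i}" for i in np.argsort(anchor, kind="stable")]
        assert layout.sample_order == expected

    def test_too_few_genes_rejected(self):
        m, _ = self._layout_matrix()
        with pytest.raises(ValueError, match="at least 2"):
            sl.heatmap_layout(m, ["g1"], "CDH1")
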