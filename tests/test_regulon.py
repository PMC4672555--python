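"""MI estimation, DPI, network consensus, maxmean scoring, MARINa, ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from screenkit import regulon as rg
from screenkit import synthetic as syn

from conftest import truth_regulon


class TestPreprocess:
    def test_columns_share_distribution_after_qnorm(self, rng):
        expr = pd.DataFrame(
            rng.normal(loc=[[0], [5]], scale=[[1], [4]], size=(2, 40)).repeat(10, 0)
            + rng.normal(size=(20, 40)),
            index=[f"g{i}" for i in range(20)],
        )
        out = rg.preprocess_expression(expr, iqr_cutoff=0.0)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        ref = np.tile(sorted_cols[:, [0]], (1, sorted_cols.shape[1]))
        np.testing.assert_allclose(sorted_cols, ref, atol=1e-9)

    def test_duplicate_genes_keep_highest_iqr(self, rng):
        flat = np.full(10, 1.0) + rng.normal(scale=0.01, size=10)
        spread = np.linspace(-3, 3, 10)
        expr = pd.DataFrame([flat, spread, rng.normal(size=10), rng.normal(size=10)],
                            index=["dup", "dup", "a", "b"])
        out = rg.preprocess_expression(expr, iqr_cutoff=0.0)
        assert (out.index == ["dup", "a", "b"]).sum() == 3 or not out.index.has_duplicates
        kept = out.loc["dup"]
        assert kept.max() - kept.min() > 1.0  # the wide copy survived

    def test_low_iqr_rows_dropped_and_floor(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 30)), index=list("abcde"))
        # constant AND always top-ranked: maps to the same normalized value
        # in every column, so its post-normalization IQR is exactly 0
        expr.loc["a"] = 100.0
        out = rg.preprocess_expression(expr, iqr_cutoff=0.5)
        assert "a" not in out.index
        with pytest.raises(ValueError, match="IQR filter"):
            rg.preprocess_expression(expr, iqr_cutoff=1e6)


class TestMutualInformation:
    @pytest.mark.parametrize("estimator", ["adaptive_partition", "rank_bins"])
    def test_gaussian_closed_form(self, estimator):
        # MI of a bivariate normal is -0.5*ln(1-rho^2)
        rng = np.random.default_rng(42)
        for rho in (0.5, 0.8):
            cov = [[1, rho], [rho, 1]]
            x, y = rng.multivariate_normal([0, 0], cov, size=4000).T
            est = rg.mutual_information(x, y, estimator=estimator)
            truth = -0.5 * np.log(1 - rho**2)
            assert est == pytest.approx(truth, rel=0.3)

    def test_independent_near_zero_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=(2, 3000))
        mi0 = rg.mutual_information(x, y)
        assert mi0 < 0.02
        # rank-based estimate is invariant to strictly monotone transforms
        z = 0.7 * x + 0.3 * rng.normal(size=3000)
        a = rg.mutual_information(x, z)
        b = rg.mutual_information(np.exp(x), z**3)
        assert a == pytest.approx(b, rel=1e-9)

    def test_constant_vector_warns_zero(self, caplog):
        with caplog.at_level("WARNING"):
            mi = rg.mutual_information(np.ones(50), np.arange(50.0))
        assert mi == 0.0
        assert any("constant" in r.message for r in caplog.records)

    def test_unknown_estimator(self):
        with pytest.raises(ValueError, match="estimator"):
            rg.mutual_information(np.arange(20.0), np.arange(20.0), estimator="x")


class TestMiThreshold:
    def test_monotone_in_p(self, rng):
        x = rng.normal(size=(40, 120))
        t_loose = rg.mi_threshold(x, 1e-2, n_null=2000, seed=0)
        t_tight = rg.mi_threshold(x, 1e-6, n_null=2000, seed=0)
        assert 0 < t_loose < t_tight

    def test_separates_signal_from_null(self, rng):
        x = rng.normal(size=(30, 200))
        thr = rg.mi_threshold(x, 1e-4, n_null=3000, seed=1)
        a = rng.normal(size=200)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(size=200)
        assert rg.mutual_information(a, b) > thr
        assert rg.mutual_information(x[0], x[1]) < thr


class TestDpi:
    def test_weakest_triangle_edge_removed(self):
        edges = {("h", "t"): 0.5, ("h", "u"): 0.4, ("t", "u"): 0.1}
        pruned = rg.dpi_prune(edges)
        assert set(pruned) == {("h", "t"), ("h", "u")}

    def test_tie_keeps_all(self):
        edges = {("a", "b"): 0.3, ("b", "c"): 0.3, ("a", "c"): 0.3}
        assert set(rg.dpi_prune(edges)) == set(map(tuple, map(sorted, edges)))

    def test_tolerance_spares_near_ties(self):
        edges = {("a", "b"): 0.30, ("b", "c"): 0.29, ("a", "c"): 0.28}
        assert len(rg.dpi_prune(edges, tolerance=0.0)) == 2
        assert len(rg.dpi_prune(edges, tolerance=0.10)) == 3

    def test_chain_without_triangle_untouched(self):
        edges = {("a", "b"): 0.1, ("b", "c"): 0.9}
        assert rg.dpi_prune(edges) == edges

    def test_idempotent_on_random_graphs(self, rng):
        nodes = [f"n{i}" for i in range(8)]
        for _ in range(20):
            edges = {}
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.5:
                    edges[(a, b)] = float(rng.random())
            once = rg.dpi_prune(edges)
            twice = rg.dpi_prune(once)
            assert once == twice

    def test_marks_applied_against_original(self):
        # two triangles sharing the weak edge: removal decided on the full
        # graph, so both triangles see the same weakest edge
        edges = {
            ("a", "b"): 0.05, ("a", "c"): 0.5, ("b", "c"): 0.5,
            ("a", "d"): 0.6, ("b", "d"): 0.6,
        }
        pruned = rg.dpi_prune(edges)
        assert ("a", "b") not in pruned
        assert len(pruned) == 4


class TestMaxmean:
    @pytest.mark.parametrize(
        "v,score",
        [
            ([1.0, 2.0, 3.0], 2.0),  # all positive: plain mean
            ([-1.0, -2.0, -3.0], -2.0),
            ([2.0, -1.0, 0.0], 2.0 / 3.0),  # positives dominate
            ([1.0, -1.0], 0.5),  # exact tie -> s_plus wins
        ],
    )
    def test_hand_cases(self, v, score):
        got, s_plus, s_minus = rg.maxmean(v)
        assert got == pytest.approx(score)
        assert s_plus == pytest.approx(np.maximum(v, 0).mean())
        assert s_minus == pytest.approx(np.maximum(np.negative(v), 0).mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rg.maxmean([])


class TestActivityScores:
    def test_hand_example_with_signs(self):
        expr = pd.DataFrame(
            {"s1": [1.0, -1.0], "s2": [-1.0, 1.0], "s3": [0.0, 0.0]},
            index=["t_act", "t_rep"],
        )
        reg = rg.Regulon(
            hub="H",
            targets=pd.DataFrame(
                {"mode": [0.9, -0.9], "confidence": [1.0, 1.0]},
                index=pd.Index(["t_act", "t_rep"], name="target"),
            ),
        )
        out = rg.activity_scores(expr, reg, signed=True)
        # with sign adjustment both genes agree: s1 active, s2 inactive
        assert out.loc["s1", "score"] > 0 > out.loc["s2", "score"]
        assert out.loc["s1", "score"] == pytest.approx(-out.loc["s2", "score"])
        unsigned = rg.activity_scores(expr, reg, signed=False)
        assert abs(unsigned.loc["s1", "score"]) < out.loc["s1", "score"]

    def test_planted_groups_separate(self, planted_expression):
        expr = planted_expression["expr"]
        reg = truth_regulon(planted_expression["truth"])
        out = rg.activity_scores(expr, reg)
        a = out.loc[[s for s in out.index if s.startswith("A_")], "score"]
        b = out.loc[[s for s in out.index if s.startswith("B_")], "score"]
        assert a.mean() > b.mean()
        t, p = sps.ttest_ind(a, b)
        assert p < 1e-6
        assert out.attrs["regulon_coverage"] == 1.0

    def test_missing_genes_coverage_warning(self, planted_expression, caplog):
        reg = truth_regulon(planted_expression["truth"])
        keep = planted_expression["expr"].drop(index=reg.genes[: len(reg.genes) // 2])
        with caplog.at_level("WARNING"):
            out = rg.activity_scores(keep, reg)
        assert out.attrs["regulon_coverage"] < 0.7
        assert any("regulon genes detected" in r.message for r in caplog.records)


@pytest.fixture(scope="module")
def compendium():
    cfg = syn.SimExprConfig(
        n_genes=241, n_targets=20, n_per_group=150, hub_activity_shift=0.0,
        seed=23,
    )
    expr, truth = syn.gen_expression(cfg)
    return expr, truth


class TestNetwork:
    def test_planted_regulon_recovered(self, compendium):
        expr, truth = compendium
        net = rg.build_network(expr, ["HUB"], rg.NetworkConfig(seed=1))
        reg = rg.extract_regulon(net, expr, "HUB")
        found = set(reg.genes)
        planted = set(truth.regulon_truth)
        tp = len(found & planted)
        precision = tp / len(found) if found else 0.0
        recall = tp / len(planted)
        assert precision >= 0.8
        assert recall >= 0.8
        # recovered modes carry the planted signs
        common = sorted(found & planted)
        signs = np.sign(reg.modes().loc[common].to_numpy())
        planted_signs = np.array([truth.regulon_truth[t] for t in common])
        assert (signs == planted_signs).mean() >= 0.9

    def test_deterministic(self, compendium):
        expr, _ = compendium
        n1 = rg.build_network(expr, ["HUB"], rg.NetworkConfig(seed=1))
        n2 = rg.build_network(expr, ["HUB"], rg.NetworkConfig(seed=1))
        pd.testing.assert_frame_equal(n1, n2)

    def test_unknown_regulator_rejected(self, compendium):
        expr, _ = compendium
        with pytest.raises(ValueError, match="regulators"):
            rg.build_network(expr, ["NOPE"], rg.NetworkConfig())

    def test_hub_not_own_target(self):
        with pytest.raises(ValueError, match="own regulon"):
            rg.Regulon(
                hub="H",
                targets=pd.DataFrame(
                    {"mode": [0.5], "confidence": [1.0]},
                    index=pd.Index(["H"], name="target"),
                ),
            )


class TestMarina:
    def test_planted_shift_significant(self, planted_expression):
        expr = planted_expression["expr"]
        reg = truth_regulon(planted_expression["truth"])
        labels = pd.Series(
            [s.split("_")[0] for s in expr.columns], index=expr.columns
        )
        res = rg.marina_test(expr, labels, reg, n_perm=500, seed=0)
        assert res.p_perm == pytest.approx(1 / 501)
        assert abs(res.nes) > 3

    def test_null_labels_not_significant(self, planted_expression, rng):
        expr = planted_expression["expr"]
        reg = truth_regulon(planted_expression["truth"])
        labels = pd.Series(
            rng.permutation([s.split("_")[0] for s in expr.columns]),
            index=expr.columns,
        )
        res = rg.marina_test(expr, labels, reg, n_perm=300, seed=0)
        assert res.p_perm > 0.05

    def test_group_t_matches_scipy(self, rng):
        x = rng.normal(size=(6, 20))
        ind = np.zeros((1, 20))
        ind[0, :8] = 1.0
        t = rg._group_t_stats(x, ind)[:, 0]
        exp = [sps.ttest_ind(row[:8], row[8:]).statistic for row in x]
        np.testing.assert_allclose(t, exp, rtol=1e-10)

    def test_validation(self, planted_expression):
        expr = planted_expression["expr"]
        reg = truth_regulon(planted_expression["truth"])
        labels = pd.Series("A", index=expr.columns)
        with pytest.raises(ValueError, match="2 groups"):
            rg.marina_test(expr, labels, reg)


class TestScoreAnova:
    def test_textbook_oracle(self):
        # 8 points, two groups, one numeric covariate; compare against the
        # closed-form nested-model F computed with plain linear algebra
        y = pd.Series([1.0, 2.0, 1.5, 2.5, 3.0, 4.0, 3.5, 4.5])
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=y.index)
        cov = pd.DataFrame({"x": [0.1, 0.4, 0.2, 0.8, 0.3, 0.9, 0.5, 0.7]},
                           index=y.index)
        fit = rg.score_anova(y, g, cov)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            r = y.to_numpy() - X @ beta
            return float(r @ r)

        Xr = np.column_stack([np.ones(8), (g == "b").astype(float)])
        Xf = np.column_stack([Xr, cov["x"]])
        rss_r, rss_f = rss(Xr), rss(Xf)
        f_exp = ((rss_r - rss_f) / 1) / (rss_f / (8 - 3))
        assert fit.f_stat == pytest.approx(f_exp, rel=1e-9)
        assert fit.p == pytest.approx(float(sps.f.sf(f_exp, 1, 5)), rel=1e-9)
        assert fit.rss_reduced == pytest.approx(rss_r, rel=1e-9)

    def test_aliased_covariate_contributes_nothing(self, caplog):
        y = pd.Series(np.arange(8.0))
        g = pd.Series(["a"] * 4 + ["b"] * 4, index=y.index)
        cov = pd.DataFrame({"same": (g == "b").astype(float)}, index=y.index)
        with caplog.at_level("WARNING"):
            fit = rg.score_anova(y, g, cov)
        assert fit.delta_df == 0
        assert fit.f_stat == 0.0 and fit.p == 1.0
        assert any("rank-deficient" in r.message for r in caplog.records)

    def test_group_only_model(self):
        y = pd.Series([1.0, 1.2, 0.9, 5.0, 5.1, 4.9])
        g = pd.Series(["a"] * 3 + ["b"] * 3, index=y.index)
        fit = rg.score_anova(y, g)
        assert fit.r2_reduced > 0.95
        assert fit.delta_df == 0 and fit.p == 1.0
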