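"""Consolidation, regressions, PCR, and candidate selection."""

import numpy as np
import pandas as pd
import pytest

from eist.screen import (
    consolidate_de_lists,
    electrode_site_expression,
    enumerate_gene_sets,
    gene_set_pcr,
    pca_inspect,
    predict_metric,
    select_candidates,
    single_gene_regression,
)


def _table(genes, lfcs):
    return pd.DataFrame({"gene": genes, "lfc": lfcs})


class TestConsolidate:
    def test_max_abs_lfc_rule_keeps_sign(self):
        out = consolidate_de_lists(
            {"24h": _table(["A", "B"], [1.0, 0.8]),
             "1wk": _table(["B", "C"], [-1.5, 0.7])}
        )
        by_gene = {c.gene: c for c in out}
        assert set(by_gene) == {"A", "B", "C"}
        assert by_gene["B"].lfc == -1.5
        assert by_gene["B"].timepoints == ("1wk", "24h")

    def test_disjoint_union_arithmetic(self):
        out = consolidate_de_lists(
            {"a": _table(["g1", "g2", "g3"], [1] * 3),
             "b": _table(["g4", "g5"], [1] * 2),
             "c": _table(["g6"], [1])}
        )
        assert len(out) == 6

    def test_random_lists_match_set_union_oracle(self):
        rng = np.random.default_rng(0)
        pools = {
            tp: list(rng.choice(200, size=rng.integers(10, 60), replace=False))
            for tp in ("24h", "1wk", "6wk")
        }
        tables = {
            tp: _table([f"g{i}" for i in ids], rng.normal(0, 1, len(ids)))
            for tp, ids in pools.items()
        }
        out = consolidate_de_lists(tables)
        union = set().union(*({f"g{i}" for i in ids} for ids in pools.values()))
        assert {c.gene for c in out} == union

    def test_duplicates_within_table_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            consolidate_de_lists({"24h": _table(["A", "A"], [1, 2])})


class TestSiteExpression:
    def test_composition_identity_single_sample(self):
        from eist.normalization import mna_normalize
        from eist.simulate import SimulationConfig, default_panel, simulate_spot_dataset
        from eist.spatial import select_cluster

        ds, _ = simulate_spot_dataset(
            SimulationConfig(grid_shape=(10, 10), seed=1), default_panel(10)
        )

        class S:
            name = "s"
            dataset = ds
            implanted = True

        expr = electrode_site_expression([S()], ["Gfap"])
        cluster = select_cluster(ds.spots, ds.tract, 300.0)
        expected = mna_normalize(ds, cluster).gene_mna.loc["Gfap"]
        assert expr.loc["Gfap", "s"] == pytest.approx(expected)

    def test_missing_gene_warns_and_zero(self):
        from eist.simulate import SimulationConfig, default_panel, simulate_spot_dataset

        ds, _ = simulate_spot_dataset(
            SimulationConfig(grid_shape=(8, 8), seed=2), default_panel(5)
        )

        class S:
            name = "s"
            dataset = ds
            implanted = True

        with pytest.warns(UserWarning, match="absent"):
            expr = electrode_site_expression([S()], ["NotAGene"])
        assert expr.loc["NotAGene", "s"] == 0.0


class TestSingleGeneRegression:
    def test_perfect_fit(self):
        x = np.arange(8.0)
        res = single_gene_regression(x, 2 * x, "g", "MUA")
        assert res.r2 == pytest.approx(1.0)
        assert res.p < 1e-10
        assert res.slope == pytest.approx(2.0)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.normal(0, 1, (2, 10))
            res = single_gene_regression(x, y, "g", "M")
            assert abs(res.r2 - np.corrcoef(x, y)[0, 1] ** 2) < 1e-12

    def test_affine_invariance_of_r2(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, (2, 12))
        r0 = single_gene_regression(x, y, "g", "M").r2
        r1 = single_gene_regression(5 * x - 3, 0.1 * y + 7, "g", "M").r2
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_missing_metrics_dropped(self):
        x = np.arange(6.0)
        y = 2 * x
        y[0] = np.nan
        assert single_gene_regression(x, y, "g", "M").n == 5

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="at least 3"):
            single_gene_regression([1, 2], [1, 2], "g", "M")
        with pytest.warns(UserWarning, match="zero variance"):
            assert single_gene_regression([1, 1, 1, 1], [1, 2, 3, 4], "g", "M") is None


class TestPcaInspect:
    def test_identical_samples_equal_scores(self):
        m = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [4.0, 0.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
        scores, _ = pca_inspect(m)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"], atol=1e-12)

    def test_rank_one_explains_everything(self):
        base = np.array([1.0, -2.0, 0.5])
        m = pd.DataFrame(np.outer(base, [1.0, 2.0, 5.0, -1.0]),
                         index=["g1", "g2", "g3"])
        _, frac = pca_inspect(m)
        assert frac[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(0, 1, (12, 6)))
        scores, frac = pca_inspect(m)
        X = m.to_numpy().T
        Xc = X - X.mean(axis=0)
        w, v = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        for j in (0, 1):
            ref = Xc @ v[:, order[j]]
            got = scores.iloc[:, j].to_numpy()
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="2 samples"):
            pca_inspect(pd.DataFrame({"a": [1.0, 2.0]}))


class TestEnumerateGeneSets:
    def test_binomial_count(self):
        pool = ["a", "b", "c", "d"]
        assert len(list(enumerate_gene_sets(pool, 2))) == 6

    def test_cap_truncates_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = list(enumerate_gene_sets(list("abcde"), 2, cap=3))
        assert len(out) == 3

    def test_count_matches_combinatorics_oracle(self):
        from math import comb

        rng = np.random.default_rng(6)
        for _ in range(5):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, n + 1))
            pool = [f"g{i}" for i in range(n)]
            assert len(list(enumerate_gene_sets(pool, k))) == comb(n, k)

    def test_deterministic_lexicographic(self):
        out = list(enumerate_gene_sets(["c", "a", "b"], 2))
        assert out == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_oversized_subset_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            list(enumerate_gene_sets(["a"], 2))


class TestGeneSetPcr:
    def test_singleton_equals_single_gene_regression(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(10, 3, 8)
            y = 0.5 * x + rng.normal(0, 1, 8)
            r_single = single_gene_regression(x, y, "g", "M").r2
            expr = pd.DataFrame([x], index=["g"])
            r_pcr = gene_set_pcr(expr, y, "M").r2
            assert abs(r_single - r_pcr) < 1e-9

    def test_duplicated_gene_degenerate_case(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 8)
        y = 2 * x + rng.normal(0, 0.3, 8)
        expr = pd.DataFrame([x, 3 * x + 5], index=["a", "b"])
        res = gene_set_pcr(expr, y, "M")
        assert res.explained_var == pytest.approx(1.0)
        assert res.r2 == pytest.approx(
            single_gene_regression(x, y, "a", "M").r2, abs=1e-9
        )

    def test_common_factor_beats_or_matches_single_genes(self):
        # when y depends on the set's common factor, PC1 regression is
        # competitive with the best member gene; at n=8 the max over
        # members enjoys selection bias, so a few draws may beat PCR
        rng = np.random.default_rng(9)
        wins = 0
        for _ in range(50):
            f = rng.normal(0, 1, 8)
            genes = {f"g{i}": f + rng.normal(0, 0.3, 8) for i in range(3)}
            y = 2 * f + rng.normal(0, 0.4, 8)
            expr = pd.DataFrame(genes).T
            r_pcr = gene_set_pcr(expr, y, "M").r2
            r_best = max(
                single_gene_regression(expr.loc[g], y, g, "M").r2
                for g in expr.index
            )
            wins += r_pcr >= r_best - 0.05
        assert wins >= 45

    def test_zero_variance_gene_dropped(self):
        x = np.arange(8.0)
        expr = pd.DataFrame([x, np.ones(8)], index=["a", "flat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = gene_set_pcr(expr, 2 * x, "M")
        assert res.genes == ("a",)

    def test_mean_abs_lfc_attached(self):
        x = np.arange(8.0)
        expr = pd.DataFrame([x, x + 1], index=["a", "b"])
        res = gene_set_pcr(expr, x, "M", lfcs={"a": 1.0, "b": -3.0})
        assert res.mean_abs_lfc == pytest.approx(2.0)


class TestSelectCandidates:
    @staticmethod
    def _results(labels, lfcs, r2s):
        return pd.DataFrame({"label": labels, "lfc": lfcs, "r2": r2s})

    def test_dominating_result_ranked_first(self):
        res = self._results(["top", "x", "y", "z", "w"],
                            [3.0, 1.0, 0.5, 0.2, 0.1],
                            [0.9, 0.5, 0.4, 0.3, 0.2])
        sel = select_candidates(res, k=4)
        assert sel.table["label"].iloc[0] == "top"

    def test_min_rule_zeroes_one_sided_results(self):
        # highest R^2 but minimal |lfc| -> score 0 -> ranked below
        # anything with positive score
        res = self._results(["onesided", "lowr2", "a", "b", "c", "d"],
                            [0.01, 1.0, 1.0, 1.2, 0.8, 0.9],
                            [0.99, 0.30, 0.5, 0.6, 0.45, 0.55])
        sel = select_candidates(res, k=4)
        assert "onesided" not in sel.table["label"].tolist()
        assert set(sel.table["label"]) == {"a", "b", "c", "d"}

    def test_fewer_than_k_warns(self):
        res = self._results(["a", "b"], [1.0, 2.0], [0.1, 0.2])
        with pytest.warns(UserWarning, match="returning all"):
            sel = select_candidates(res, k=4)
        assert len(sel.table) == 2

    def test_k_bounds(self):
        res = self._results(list("abcdefgh"), np.arange(8.0), np.arange(8.0) / 8)
        with pytest.raises(ValueError):
            select_candidates(res, k=3)
        with pytest.raises(ValueError):
            select_candidates(res, k=8)

    def test_deterministic_tiebreak(self):
        res = self._results(["b", "a", "c", "d", "e"],
                            [1.0, 1.0, 1.0, 1.0, 1.0],
                            [0.5, 0.5, 0.5, 0.5, 0.5])
        s1 = select_candidates(res, k=4).table["label"].tolist()
        s2 = select_candidates(res.iloc[::-1].reset_index(drop=True),
                               k=4).table["label"].tolist()
        assert s1 == s2 == sorted(s1)


class TestPredictMetric:
    def test_perfect_fit_reproduces_y(self):
        x = np.arange(8.0)
        y = 3 * x + 2
        res = single_gene_regression(x, y, "g", "M")
        expr = pd.DataFrame([x], index=["g"], columns=[f"s{i}" for i in range(8)])
        out = predict_metric(res, expr, y)
        np.testing.assert_allclose(out["fitted"], y, atol=1e-10)
        np.testing.assert_allclose(out["residual"], 0.0, atol=1e-10)

    def test_r2_recomputed_from_fit_matches_stored(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 8)
        y = x + rng.normal(0, 0.5, 8)
        res = single_gene_regression(x, y, "g", "M")
        expr = pd.DataFrame([x], index=["g"])
        out = predict_metric(res, expr, y)
        ss_res = (out["residual"] ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert abs((1 - ss_res / ss_tot) - res.r2) < 1e-12

    def test_pcr_prediction_consistent(self):
        rng = np.random.default_rng(11)
        X = rng.normal(5, 2, (3, 8))
        y = X.mean(axis=0) + rng.normal(0, 0.2, 8)
        expr = pd.DataFrame(X, index=["a", "b", "c"])
        res = gene_set_pcr(expr, y, "M")
        out = predict_metric(res, expr, y)
        ss_res = (out["residual"] ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert abs((1 - ss_res / ss_tot) - res.r2) < 1e-9

    def test_missing_gene_errors(self):
        x = np.arange(8.0)
        res = single_gene_regression(x, x, "g", "M")
        with pytest.raises(KeyError, match="missing"):
            predict_metric(res, pd.DataFrame([x], index=["other"]))
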