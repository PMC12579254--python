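"""TMM, log-CPM, moderated-t DE, markers, Fisher meta, Jaccard."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcpmap._stats import bh_adjust
from mcpmap.normalization_de import (
    consensus_markers,
    detect_markers,
    differential_expression,
    fisher_meta,
    jaccard_agreement,
    logcpm,
    tmm_factors,
)


def tmm_oracle(X, logratio_trim=0.30, sum_trim=0.05):
    """Independently coded brute-force TMM (explicit loops/sorting)."""
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=0)
    f75 = []
    for j in range(X.shape[1]):
        f75.append(np.quantile(X[:, j], 0.75) / lib[j])
    f75 = np.array(f75)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = []
    for j in range(X.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        M, A, w = [], [], []
        for g in range(X.shape[0]):
            if X[g, j] > 0 and X[g, ref] > 0:
                pj = X[g, j] / lib[j]
                pr = X[g, ref] / lib[ref]
                M.append(np.log2(pj / pr))
                A.append(0.5 * np.log2(pj * pr))
                w.append(1.0 / ((lib[j] - X[g, j]) / (lib[j] * X[g, j])
                                + (lib[ref] - X[g, ref]) / (lib[ref] * X[g, ref])))
        M, A, w = map(np.array, (M, A, w))
        n = len(M)
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        loL = np.floor(n * logratio_trim) + 1
        loS = np.floor(n * sum_trim) + 1
        keep = ((rM >= loL) & (rM <= n + 1 - loL)
                & (rA >= loS) & (rA <= n + 1 - loS))
        factors.append(2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10, 50, 3, 200, 7])
        X = pd.DataFrame({"a": col, "b": col, "c": col})
        np.testing.assert_allclose(tmm_factors(X), 1.0, atol=1e-12)

    def test_pure_depth_scaling_absorbed_by_library_size(self):
        col = np.array([10, 50, 4, 200, 8, 33])
        X = pd.DataFrame({"a": col, "b": 2 * col})
        np.testing.assert_allclose(tmm_factors(X), 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            X = rng.negative_binomial(5, 0.3, size=(300, 5)) + \
                rng.poisson(2, size=(300, 5))
            got = tmm_factors(pd.DataFrame(X)).to_numpy()
            np.testing.assert_allclose(got, tmm_oracle(X), atol=1e-10)

    def test_all_zero_sample_rejected(self):
        X = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(X)


class TestLogCPM:
    def test_prior_count_arithmetic(self):
        # library exactly 1e6, factor 1 -> log2((0 + 0.5)/1e6 * 1e6) = -1
        X = pd.DataFrame({"s1": [0, 1_000_000], "s2": [0, 1_000_000]},
                         index=["gA", "gB"])
        out = logcpm(X, prior_count=0.5)
        assert out.loc["gA", "s1"] == pytest.approx(-1.0)

    def test_scale_invariance_without_prior(self):
        X = pd.DataFrame({"s1": [10, 90], "s2": [20, 80]})
        a = logcpm(X, prior_count=0.0)
        b = logcpm(2 * X, prior_count=0.0)
        pd.testing.assert_frame_equal(a, b)

    def test_monotone_in_count(self):
        X = pd.DataFrame({"s1": [1, 10, 100, 1000]})
        v = logcpm(X).to_numpy().ravel()
        assert (np.diff(v) > 0).all()


class TestDifferentialExpression:
    def test_equal_group_means_give_zero_t(self):
        y = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["g"],
                         columns=list("abcd"))
        sig = differential_expression(y, ["HF", "HF", "NF", "NF"])
        assert sig.table.loc["g", "t"] == pytest.approx(0.0)
        assert sig.table.loc["g", "p"] == pytest.approx(1.0)

    def test_zero_prior_df_equals_pooled_t_test(self, rng):
        Y = pd.DataFrame(rng.normal(size=(40, 12)))
        groups = np.array(["HF"] * 6 + ["NF"] * 6)
        sig = differential_expression(Y, groups, prior_df=0.0,
                                      positive_class="HF")
        t_ref, p_ref = stats.ttest_ind(Y.to_numpy()[:, :6].T,
                                       Y.to_numpy()[:, 6:].T, equal_var=True)
        np.testing.assert_allclose(sig.table["t"], t_ref, atol=1e-10)
        np.testing.assert_allclose(sig.table["p"], p_ref, atol=1e-10)

    def test_planted_logfc_recovered(self, rng):
        n = 20
        effects = np.full(50, 2.0)
        Y = rng.normal(0, 0.5, size=(50, 2 * n))
        Y[:, :n] += effects[:, None]
        sig = differential_expression(pd.DataFrame(Y),
                                      ["HF"] * n + ["NF"] * n)
        assert np.abs(sig.table["logFC"].mean() - 2.0) < 0.1
        assert (np.abs(sig.table["logFC"] - 2.0) < 0.45).all()

    def test_confounded_design_rejected(self):
        y = pd.DataFrame(np.ones((3, 6)))
        cov = pd.DataFrame({"x": [1, 1, 1, 0, 0, 0]})
        with pytest.raises(ValueError, match="confounded"):
            differential_expression(y, ["HF"] * 3 + ["NF"] * 3, covariates=cov)

    def test_null_pvalues_uniform(self, rng):
        Y = pd.DataFrame(rng.normal(size=(2000, 30)))
        labels = np.array(["HF"] * 15 + ["NF"] * 15)
        sig = differential_expression(Y, labels)
        ks = stats.kstest(sig.table["p"], "uniform")
        assert ks.pvalue > 0.01


class TestDetectMarkers:
    def test_thresholds_applied(self, rng):
        # gene "hi" is ~16x up in Fib (logFC ~4); gene "mid" ~2.5x (logFC ~1.3)
        n = 12
        base = rng.poisson(100, size=(30, 3 * n))
        counts = pd.DataFrame(base, index=[f"g{i}" for i in range(30)])
        counts.loc["hi"] = rng.poisson(50, 3 * n)
        counts.loc["mid"] = rng.poisson(200, 3 * n)
        counts.iloc[-2, :n] = rng.poisson(800, n)    # hi in Fib
        counts.iloc[-1, :n] = rng.poisson(500, n)    # mid in Fib
        views = {"Fib": counts.iloc[:, :n],
                 "CM": counts.iloc[:, n:2 * n],
                 "Endo": counts.iloc[:, 2 * n:]}
        sets, sigs = detect_markers(views)
        assert "hi" in sets["Fib"]
        assert "mid" not in sets["Fib"]
        assert sigs["Fib"].table.loc["mid", "adj_p"] < 0.01  # filtered by logFC

    def test_single_celltype_rejected(self):
        with pytest.raises(ValueError):
            detect_markers({"Fib": pd.DataFrame()})

    def test_planted_markers_recovered_by_consensus(self, small_cohort):
        """Per-study batch noise wobbles single-study logFC estimates;
        the cross-study consensus recovers the planted sets."""
        by_study = {}
        for (s, ct), m in small_cohort.views.items():
            by_study.setdefault(s, {})[ct] = m
        sets, _ = consensus_markers(by_study, min_studies=2)
        for ct, truth in small_cohort.truth.marker_sets.items():
            got = sets[ct]
            jac = len(got & truth) / len(got | truth)
            assert jac >= 0.8, (ct, jac)


class TestFisherMeta:
    def test_all_ones_give_zero_statistic(self):
        P = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["g"])
        res = fisher_meta(P, min_studies=3)
        assert res.table.loc["g", "fisher_stat"] == pytest.approx(0.0)
        assert res.table.loc["g", "p"] == pytest.approx(1.0)

    def test_two_pvalues_closed_form(self):
        P = pd.DataFrame({"s1": [0.05], "s2": [0.05]}, index=["g"])
        res = fisher_meta(P, min_studies=2)
        stat = res.table.loc["g", "fisher_stat"]
        assert stat == pytest.approx(-2 * 2 * np.log(0.05), abs=1e-3)
        assert stat == pytest.approx(11.983, abs=1e-3)
        assert res.table.loc["g", "df"] == 4
        assert res.table.loc["g", "p"] == pytest.approx(
            stats.chi2.sf(stat, 4), rel=1e-12)
        assert res.table.loc["g", "p"] == pytest.approx(0.0175, abs=5e-4)

    def test_undersampled_genes_excluded(self):
        P = pd.DataFrame({"s1": [0.01, 0.01], "s2": [0.01, np.nan],
                          "s3": [0.01, np.nan]}, index=["kept", "dropped"])
        res = fisher_meta(P, min_studies=3)
        assert "kept" in res.table.index
        assert "dropped" not in res.table.index

    def test_zero_pvalue_clipped_with_warning(self):
        P = pd.DataFrame({"s1": [0.0], "s2": [0.5], "s3": [0.5]}, index=["g"])
        with pytest.warns(RuntimeWarning):
            res = fisher_meta(P, min_studies=3)
        assert np.isfinite(res.table.loc["g", "fisher_stat"])

    def test_null_combined_p_uniform(self, rng):
        P = pd.DataFrame(rng.uniform(size=(10_000, 5)))
        res = fisher_meta(P, min_studies=5)
        ks = stats.kstest(res.table["p"], "uniform")
        assert ks.pvalue > 0.01


class TestBH:
    def test_matches_step_up_definition(self, rng):
        def oracle(p):
            p = np.asarray(p)
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank_from_top in range(n, 0, -1):
                i = order[rank_from_top - 1]
                running = min(running, p[i] * n / rank_from_top)
                adj[i] = running
            return adj

        for _ in range(5):
            p = rng.uniform(size=50) ** 2
            np.testing.assert_allclose(bh_adjust(p), oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(size=100)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestJaccard:
    def test_known_values(self):
        sets = {"A": {"a", "b", "c"}, "B": {"b", "c", "d"},
                "C": {"a", "b", "c"}, "D": {"x"}}
        J = jaccard_agreement(sets)
        assert J.loc["A", "B"] == pytest.approx(0.5)
        assert J.loc["A", "C"] == 1.0
        assert J.loc["A", "D"] == 0.0
        assert (J.to_numpy() == J.to_numpy().T).all()
        assert (np.diag(J) == 1.0).all()

    def test_two_empty_sets_warn_and_give_zero(self):
        with pytest.warns(RuntimeWarning):
            J = jaccard_agreement({"A": set(), "B": set()})
        assert J.loc["A", "B"] == 0.0
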