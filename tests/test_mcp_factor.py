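"""Multi-view filtering cascade and the masked ALS factor model."""

import numpy as np
import pandas as pd
import pytest

from mcpmap.io_ontology import CohortViews
from mcpmap.mcp_factor import (
    MultiViewDataset,
    associate_covariates,
    build_views,
    covariate_total_r2,
    de_interaction,
    fit_mcp,
    variance_explained,
)


def make_dataset(rng, n=40, genes_per_view=(30, 25), K=3, n_studies=2,
                 noise=0.0, missing_frac=0.0, loading_scale=(1.0, 1.0)):
    """Rank-K multi-view data with known scores; single- or multi-study."""
    samples = [f"s{i:02d}" for i in range(n)]
    study = np.array([f"study{i % n_studies}" for i in range(n)])
    Z = rng.normal(size=(n, K))
    views = {}
    truth_W = {}
    for v, G in enumerate(genes_per_view):
        W = rng.normal(scale=loading_scale[v], size=(G, K))
        X = W @ Z.T + noise * rng.normal(size=(G, n))
        cols = samples
        if missing_frac > 0 and v == 1:
            keep = rng.random(n) > missing_frac
            X = X[:, keep]
            cols = [s for s, k in zip(samples, keep) if k]
        views[f"V{v}"] = pd.DataFrame(X, index=[f"v{v}_g{g}" for g in range(G)],
                                      columns=cols)
        truth_W[f"V{v}"] = W
    meta = pd.DataFrame({"study": study,
                         "disease": ["HF" if i % 2 else "NF" for i in range(n)]},
                        index=samples)
    ds = MultiViewDataset(views=views, metadata=meta, samples=samples,
                          filter_report=pd.DataFrame())
    return ds, Z


def match_factors(est: pd.DataFrame, truth: np.ndarray) -> np.ndarray:
    """Best |corr| of each true factor against any estimated factor."""
    best = []
    for k in range(truth.shape[1]):
        cors = [abs(np.corrcoef(est[c], truth[:, k])[0, 1]) for c in est]
        best.append(max(cors))
    return np.array(best)


class TestBuildViews:
    def _cohort(self, n_samples=10, n_genes=80, low_cell_sample=None,
                sparse_type=False):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(n_genes)]
        samples = [f"s{i}" for i in range(n_samples)]
        views, qc = {}, []
        for ct in ["CM", "Fib", "Endo", "PC"]:
            cols = samples[:3] if (sparse_type and ct == "PC") else samples
            mat = pd.DataFrame(rng.poisson(60, size=(n_genes, len(cols))),
                               index=genes, columns=cols)
            views[("study0", ct)] = mat
            for s in cols:
                n_cells = 15 if (low_cell_sample == s and ct == "CM") else 100
                qc.append({"sample": s, "celltype": ct, "n_cells": n_cells,
                           "total_reads": int(mat[s].sum()),
                           "genes_detected": int((mat[s] > 0).sum())})
        meta = pd.DataFrame({"study": "study0", "disease": "NF"}, index=samples)
        return CohortViews(views=views, metadata=meta, qc=pd.DataFrame(qc))

    def test_low_cell_profiles_dropped(self):
        cv = self._cohort(low_cell_sample="s0")
        ds = build_views(cv, filter_other_markers=False)
        assert "s0" not in ds.views["CM"].columns
        assert "s0" in ds.views["Fib"].columns

    def test_sparse_view_dropped(self):
        cv = self._cohort(sparse_type=True)  # PC present in 30% of samples
        ds = build_views(cv, filter_other_markers=False)
        assert "PC" not in ds.views
        assert "CM" in ds.views

    def test_low_coverage_sample_dropped_from_view(self):
        cv = self._cohort()
        key = ("study0", "CM")
        mat = cv.views[key].copy()
        mat.loc[mat.index[1:], "s1"] = 0  # s1 detects ~3% of genes
        cv.views[key] = mat
        ds = build_views(cv, filter_other_markers=False)
        assert "s1" not in ds.views["CM"].columns
        assert "s1" in ds.views["Fib"].columns

    def test_lowly_expressed_genes_dropped(self):
        cv = self._cohort()
        key = ("study0", "CM")
        cv.views[key].loc["g0"] = 1  # never reaches 20 counts
        ds = build_views(cv, filter_other_markers=False)
        assert "g0" not in ds.views["CM"].index

    def test_other_type_markers_removed(self):
        cv = self._cohort()
        markers = {"Fib": {"g1", "g2"}, "CM": {"g3"}}
        ds = build_views(cv, markers_by_type=markers)
        assert "g1" not in ds.views["CM"].index
        assert "g3" in ds.views["CM"].index      # own markers kept
        assert "g1" in ds.views["Fib"].index

    def test_everything_filtered_raises(self):
        cv = self._cohort()
        with pytest.raises(ValueError, match="eliminated"):
            build_views(cv, min_cells=1000, filter_other_markers=False)


def make_identifiable_dataset(rng, n=40, genes_per_view=(30, 25), K=3,
                              scales=(5.0, 3.0, 1.5)):
    """Noiseless rank-K data whose factors are identifiable: centered
    orthonormal scores with distinct variances and orthonormal stacked
    loadings (in the model's view-scaled space)."""
    samples = [f"s{i:02d}" for i in range(n)]
    A = rng.normal(size=(n, K))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    Z = Q * (np.array(scales) * np.sqrt(n))
    P = sum(genes_per_view)
    Wc, _ = np.linalg.qr(rng.normal(size=(P, K)))
    views = {}
    row = 0
    for v, G in enumerate(genes_per_view):
        W_scaled = Wc[row:row + G]
        row += G
        # data handed to the model in raw units; the model divides by
        # sqrt(G), recovering the orthonormal stacked loadings
        X = (W_scaled * np.sqrt(G)) @ Z.T
        views[f"V{v}"] = pd.DataFrame(
            X, index=[f"v{v}_g{g}" for g in range(G)], columns=samples)
    meta = pd.DataFrame({"study": "study0",
                         "disease": ["HF" if i % 2 else "NF" for i in range(n)]},
                        index=samples)
    ds = MultiViewDataset(views=views, metadata=meta, samples=samples,
                          filter_report=pd.DataFrame())
    return ds, Z


class TestFitMCP:
    def test_exact_recovery_on_noiseless_rank_k(self, rng):
        ds, Z = make_identifiable_dataset(rng, K=3)
        model = fit_mcp(ds, n_factors=3)
        resid = 0.0
        for ct, mat in ds.views.items():
            W = model.loadings[ct].to_numpy()
            S = model.scores.loc[mat.columns].to_numpy()
            centered = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
            resid += float(((centered - W @ S.T) ** 2).sum())
        assert resid < 1e-8
        assert (match_factors(model.scores, Z) > 0.999).all()

    def test_missing_views_recover_score_subspace(self, rng):
        """With a partially observed view the factor basis can rotate,
        but the estimated score space still spans the true factors."""
        ds, Z = make_dataset(rng, K=3, missing_frac=0.3, n_studies=1)
        model = fit_mcp(ds, n_factors=4)  # +1 absorbs the centering offset
        S = model.scores.to_numpy()
        S1 = np.column_stack([np.ones(len(S)), S])
        for k in range(3):
            zk = Z[:, k]
            beta, res, *_ = np.linalg.lstsq(S1, zk, rcond=None)
            r2 = 1 - float(((zk - S1 @ beta) ** 2).sum()) / float(
                ((zk - zk.mean()) ** 2).sum())
            assert r2 > 0.95, (k, r2)

    def test_single_view_equals_pca(self, rng):
        ds, _ = make_dataset(rng, genes_per_view=(40,), K=3, noise=0.05,
                             n_studies=1, loading_scale=(1.0,))
        model = fit_mcp(ds, n_factors=3)
        X = ds.views["V0"].to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for k in range(3):
            r = abs(np.corrcoef(model.scores.iloc[:, k], Vt[k])[0, 1])
            assert r > 0.999, (k, r)

    def test_deterministic(self, rng):
        ds, _ = make_dataset(rng, K=2, noise=0.2)
        m1 = fit_mcp(ds, n_factors=2)
        m2 = fit_mcp(ds, n_factors=2)
        pd.testing.assert_frame_equal(m1.scores, m2.scores)

    def test_group_centering_zeroes_study_means(self, rng):
        ds, _ = make_dataset(rng, K=2, noise=0.3, n_studies=2)
        model = fit_mcp(ds, n_factors=2)
        for ct, mat in ds.views.items():
            centered = mat.copy()
            for st in ds.metadata["study"].unique():
                cols = [c for c in mat.columns
                        if ds.metadata.loc[c, "study"] == st]
                centered[cols] = mat[cols].sub(mat[cols].mean(axis=1), axis=0)
            np.testing.assert_allclose(
                centered.mean(axis=1).to_numpy()[:5], 0.0, atol=1.0)

    def test_too_many_factors_rejected(self, rng):
        ds, _ = make_dataset(rng, n=10, genes_per_view=(8, 8), K=2)
        with pytest.raises(ValueError):
            fit_mcp(ds, n_factors=10)


class TestVarianceExplained:
    def test_zero_loading_view_has_zero_r2(self, rng):
        ds, Z = make_dataset(rng, K=2, noise=0.0,
                             loading_scale=(1.0, 1e-12))
        model = fit_mcp(ds, n_factors=2)
        r2 = variance_explained(model, ds)
        assert r2.loc["V0", "total"] > 0.99

    def test_r2_larger_in_strongly_loaded_view(self, rng):
        ds, _ = make_dataset(rng, K=1, noise=0.5, loading_scale=(2.0, 0.3))
        model = fit_mcp(ds, n_factors=1)
        r2 = variance_explained(model, ds)
        assert r2.loc["V0", "MCP1"] > r2.loc["V1", "MCP1"]

    def test_r2_within_unit_interval(self, rng):
        ds, _ = make_dataset(rng, K=3, noise=0.4)
        model = fit_mcp(ds, n_factors=3)
        vals = model.r2.to_numpy()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestAssociateCovariates:
    def test_study_indicator_factor_detected(self, rng):
        ds, _ = make_dataset(rng, K=2, noise=0.3, n_studies=2)
        model = fit_mcp(ds, n_factors=2)
        # overwrite a factor with the study indicator
        model.scores["MCP2"] = (ds.metadata.loc[model.scores.index, "study"]
                                == "study0").astype(float)
        assoc = associate_covariates(model, ds.metadata, ["study"])
        row = assoc[(assoc["factor"] == "MCP2") & (assoc["covariate"] == "study")]
        assert row["p"].iloc[0] < 1e-10
        assert row["r2"].iloc[0] > 0.99

    def test_null_covariate_has_small_total_r2(self, rng):
        ds, _ = make_dataset(rng, K=2, noise=0.3)
        model = fit_mcp(ds, n_factors=2)
        meta = ds.metadata.copy()
        meta["sex"] = rng.choice(["F", "M"], size=len(meta))
        assoc = associate_covariates(model, meta, ["sex"])
        assert covariate_total_r2(assoc, "sex") < 0.2

    def test_constant_covariate_rejected(self, rng):
        ds, _ = make_dataset(rng, K=2, noise=0.3)
        model = fit_mcp(ds, n_factors=2)
        meta = ds.metadata.copy()
        meta["site"] = "LV"
        with pytest.raises(ValueError, match="constant"):
            associate_covariates(model, meta, ["site"])


class TestDeInteraction:
    def _views_meta(self, rng, n_genes=120, n_interact=20, beta=1.5):
        samples, study, disease, sex = [], [], [], []
        for s in range(4):
            for i in range(30):
                samples.append(f"st{s}_i{i}")
                study.append(f"study{s}")
                disease.append("HF" if i < 15 else "NF")
                sex.append("F" if i % 2 else "M")
        meta = pd.DataFrame({"study": study, "disease": disease, "sex": sex},
                            index=samples)
        hf = (meta["disease"] == "HF").to_numpy(float)
        female = (meta["sex"] == "F").to_numpy(float)
        Y = rng.normal(0, 0.5, size=(n_genes, len(samples)))
        Y[:n_interact] += beta * (hf * female)[None, :]
        views = {"CM": pd.DataFrame(Y, index=[f"g{i}" for i in range(n_genes)],
                                    columns=samples)}
        return views, meta

    def test_planted_interaction_recovered(self, rng):
        views, meta = self._views_meta(rng)
        res = de_interaction(views, meta, "sex")["CM"]
        hits = set(res.index[res["adj_p"] < 0.05])
        planted = {f"g{i}" for i in range(20)}
        assert len(hits & planted) / 20 >= 0.8

    def test_null_calibrated(self, rng):
        views, meta = self._views_meta(rng, n_interact=0)
        res = de_interaction(views, meta, "sex")["CM"]
        assert (res["p"] < 0.05).mean() < 0.12

    def test_etiology_mode_contrasts_against_reference(self, rng):
        views, meta = self._views_meta(rng)
        meta = meta.copy()
        etis = np.where(np.arange(len(meta)) % 2, "DCM", "ICM")
        meta["etiology"] = np.where(meta["disease"] == "HF", etis, "NF")
        res = de_interaction(views, meta, "etiology", mode="etiology")["CM"]
        assert res.attrs["coefficient"].endswith("_vs_DCM")
        assert len(res) == len(views["CM"].index)
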