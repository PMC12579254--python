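"""Multicellular program (MCP) inference: multi-view factor analysis.

Each cell type contributes a *view* (genes x samples); samples may miss
views.  After the filter cascade (pseudobulk cell count, view coverage,
gene expression, cross-cell-type marker removal, per-sample gene
coverage) and TMM/log-CPM normalization, a K-factor model is fitted by
masked alternating least squares:

    minimize  sum_v || M_v * (X_v - W_v Z') ||^2 / p_v

with per-study, per-gene centering (group-wise centering), per-view
scaling ``1/sqrt(p_v)`` so large views do not dominate, and the mask
``M_v`` marking which samples carry the view.  Initialization is the SVD
of the zero-imputed concatenated matrix, so the fit is deterministic.
Factors are ordered by total explained variance; each factor is oriented
so it correlates positively with disease (or, without labels, so its
largest-magnitude loading is positive), and factor scores are scaled to
unit variance with the scale absorbed into the loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .lmm import fit_random_intercept
from .normalization_de import detect_markers, logcpm, tmm_factors

__all__ = [
    "MultiViewDataset",
    "MCPModel",
    "build_views",
    "fit_mcp",
    "variance_explained",
    "associate_covariates",
    "de_interaction",
]

logger = logging.getLogger(__name__)


@dataclass
class MultiViewDataset:
    """Filtered, normalized multi-view (cell type) expression dataset."""

    views: dict                 # celltype -> genes x samples log-CPM matrix
    metadata: pd.DataFrame      # indexed by sample; must include 'study'
    samples: list               # union of samples across views (fit order)
    filter_report: pd.DataFrame

    @property
    def groups(self) -> pd.Series:
        return self.metadata.loc[self.samples, "study"]


@dataclass
class MCPModel:
    """Fitted multicellular-program factor model."""

    loadings: dict              # celltype -> genes x K loading matrix
    scores: pd.DataFrame        # samples x K factor scores
    r2: pd.DataFrame            # views x K explained variance fractions
    groups: pd.Series           # sample -> study
    centers: dict               # celltype -> genes x studies training means
    view_scale: dict = field(default_factory=dict)  # celltype -> 1/sqrt(p_v)
    converged: bool = True
    n_iter: int = 0

    @property
    def n_factors(self) -> int:
        return self.scores.shape[1]

    def factor_names(self) -> list:
        return list(self.scores.columns)

    def disease_factors(self, metadata: pd.DataFrame, n: int = 2) -> list:
        """The n factors most associated with disease (smallest ANOVA p)."""
        labels = metadata.loc[self.scores.index, "disease"]
        ps = {}
        for k in self.scores.columns:
            groups = [self.scores.loc[labels == lv, k] for lv in labels.unique()]
            ps[k] = stats.f_oneway(*groups).pvalue
        ranked = sorted(ps, key=lambda k: ps[k])[:n]
        # report in total-variance order among the selected
        return [k for k in self.scores.columns if k in ranked]


def build_views(cohort, min_cells: int = 20, view_min_sample_frac: float = 0.40,
                view_min_genes: int = 50, gene_min_count: int = 20,
                gene_min_sample_frac: float = 0.40,
                sample_min_gene_frac: float = 0.97,
                markers_by_type: dict | None = None,
                filter_other_markers: bool = True) -> MultiViewDataset:
    """Apply the filter cascade and per-study normalization.

    Order: pseudobulk profiles from < ``min_cells`` cells are dropped;
    views present in < 40% of samples or with <= 50 genes are dropped;
    genes never reaching ``gene_min_count`` in any sample, or detected in
    < 40% of the view's samples, are dropped; markers of *other* cell
    types are removed; finally samples with < 97% of the view's genes
    detected are dropped from that view.
    """
    meta = cohort.metadata
    n_patients = len(meta)
    qc = cohort.qc
    cell_lookup = {}
    if len(qc):
        cell_lookup = {(r["sample"], r["celltype"]): r["n_cells"]
                       for _, r in qc.iterrows()}

    # group per-study matrices by cell type, dropping low-cell profiles
    by_type: dict = {}
    report = []
    for (study, ct), mat in cohort.views.items():
        keep = [c for c in mat.columns
                if cell_lookup.get((c, ct), min_cells) >= min_cells]
        report.append({"view": ct, "study": study, "step": "profile_min_cells",
                       "removed": mat.shape[1] - len(keep)})
        if keep:
            by_type.setdefault(ct, []).append((study, mat[keep]))

    if markers_by_type is None and filter_other_markers:
        markers_by_type = _consensus_markers(cohort, min_cells, cell_lookup)

    views: dict = {}
    for ct, mats in by_type.items():
        genes = mats[0][1].index
        for _, m in mats[1:]:
            genes = genes.intersection(m.index)
        counts = pd.concat([m.loc[genes] for _, m in mats], axis=1)
        n_samp = counts.shape[1]
        if n_samp < view_min_sample_frac * n_patients:
            report.append({"view": ct, "study": "all", "step": "view_coverage",
                           "removed": n_samp})
            continue
        # gene filters on counts
        X = counts.to_numpy()
        keep_genes = ((X.max(axis=1) >= gene_min_count)
                      & ((X > 0).mean(axis=1) >= gene_min_sample_frac))
        report.append({"view": ct, "study": "all", "step": "gene_filter",
                       "removed": int((~keep_genes).sum())})
        counts = counts.loc[keep_genes]
        if counts.shape[0] <= view_min_genes:
            report.append({"view": ct, "study": "all", "step": "view_min_genes",
                           "removed": counts.shape[0]})
            continue
        # per-study TMM + log-CPM
        norm_parts = []
        for study, m in mats:
            cols = [c for c in m.columns if c in counts.columns]
            if len(cols) < 2:
                continue
            sub = counts[cols]
            norm_parts.append(logcpm(sub, tmm_factors(sub)))
        expr = pd.concat(norm_parts, axis=1)
        # cross-marker filter
        if filter_other_markers and markers_by_type:
            other = set()
            for mt, genes_m in markers_by_type.items():
                if mt != ct:
                    other |= set(genes_m)
            other -= set(markers_by_type.get(ct, set()))
            n_before = expr.shape[0]
            expr = expr.loc[[g for g in expr.index if g not in other]]
            report.append({"view": ct, "study": "all", "step": "cross_marker",
                           "removed": n_before - expr.shape[0]})
        # sample coverage: fraction of the view's genes detected (count > 0)
        detected = (counts.loc[expr.index, expr.columns] > 0).mean(axis=0)
        keep_samples = detected >= sample_min_gene_frac
        report.append({"view": ct, "study": "all", "step": "sample_coverage",
                       "removed": int((~keep_samples).sum())})
        expr = expr.loc[:, keep_samples[keep_samples].index]
        if expr.shape[1] == 0:
            continue
        views[ct] = expr

    if not views:
        raise ValueError("all views eliminated by the filter cascade")
    samples = sorted({c for v in views.values() for c in v.columns})
    return MultiViewDataset(views=views, metadata=meta, samples=samples,
                            filter_report=pd.DataFrame(report))


def _consensus_markers(cohort, min_cells, cell_lookup) -> dict:
    """Per-study one-vs-rest markers, unioned across studies."""
    studies = sorted({s for s, _ in cohort.views})
    merged: dict = {}
    for study in studies:
        sv = {}
        for (s, ct), mat in cohort.views.items():
            if s != study:
                continue
            keep = [c for c in mat.columns
                    if cell_lookup.get((c, ct), min_cells) >= min_cells]
            if len(keep) >= 2:
                sv[ct] = mat[keep]
        if len(sv) < 2:
            continue
        try:
            sets, _ = detect_markers(sv)
        except ValueError:
            continue
        for ct, genes in sets.items():
            merged.setdefault(ct, set()).update(genes)
    return merged


def _prepare_matrices(dataset: MultiViewDataset):
    """Group-centered, view-scaled matrices plus masks and bookkeeping."""
    samples = dataset.samples
    groups = dataset.groups
    col_of = {s: i for i, s in enumerate(samples)}
    blocks, masks, centers, scales, row_slices = {}, {}, {}, {}, {}
    row0 = 0
    for ct, mat in dataset.views.items():
        G, _ = mat.shape
        X = np.full((G, len(samples)), np.nan)
        for c in mat.columns:
            X[:, col_of[c]] = mat[c].to_numpy()
        ctr = pd.DataFrame(index=mat.index, columns=sorted(groups.unique()),
                           dtype=float)
        for study in ctr.columns:
            cols = [col_of[s] for s in samples
                    if groups[s] == study and s in mat.columns]
            if not cols:
                continue
            mu = X[:, cols].mean(axis=1)
            ctr[study] = mu
            X[:, cols] -= mu[:, None]
        scale = 1.0 / np.sqrt(G)
        blocks[ct] = X * scale
        masks[ct] = ~np.isnan(X[0])  # per-sample view presence
        centers[ct] = ctr
        scales[ct] = scale
        row_slices[ct] = slice(row0, row0 + G)
        row0 += G
    return blocks, masks, centers, scales, row_slices, samples


def fit_mcp(dataset: MultiViewDataset, n_factors: int = 10,
            max_iter: int = 500, tol: float = 1e-6) -> MCPModel:
    """Fit the multicellular-program factor model by masked ALS.

    Deterministic: initialization is the truncated SVD of the
    zero-imputed concatenated matrix; alternating least-squares updates
    of loadings (per view, over that view's observed samples) and scores
    (per sample, over its observed views) monotonically decrease the
    masked squared error.
    """
    blocks, masks, centers, scales, row_slices, samples = _prepare_matrices(dataset)
    n = len(samples)
    total_features = sum(b.shape[0] for b in blocks.values())
    K = n_factors
    if K >= min(n, total_features):
        raise ValueError("n_factors must be < min(samples, features)")

    Xc = np.vstack([np.nan_to_num(b, nan=0.0) for b in blocks.values()])
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    Z = (Vt[:K].T * S[:K])  # n x K

    views = list(blocks)
    obs_cols = {ct: np.flatnonzero(masks[ct]) for ct in views}
    Xobs = {ct: np.nan_to_num(blocks[ct], nan=0.0) for ct in views}
    # sample -> observed-view pattern for batched score updates
    pattern = {}
    for i in range(n):
        key = tuple(ct for ct in views if masks[ct][i])
        pattern.setdefault(key, []).append(i)

    W = {ct: np.zeros((blocks[ct].shape[0], K)) for ct in views}
    prev_obj = np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        for ct in views:
            cols = obs_cols[ct]
            Zo = Z[cols]
            A = Zo.T @ Zo + 1e-12 * np.eye(K)
            W[ct] = np.linalg.solve(A, Zo.T @ Xobs[ct][:, cols].T).T
        for key, idx in pattern.items():
            if not key:
                Z[idx] = 0.0
                continue
            Wp = np.vstack([W[ct] for ct in key])
            Xp = np.vstack([Xobs[ct][:, idx] for ct in key])
            A = Wp.T @ Wp + 1e-12 * np.eye(K)
            Z[idx] = np.linalg.solve(A, Wp.T @ Xp).T
        obj = 0.0
        for ct in views:
            cols = obs_cols[ct]
            R = Xobs[ct][:, cols] - W[ct] @ Z[cols].T
            obj += float((R ** 2).sum())
        if np.isfinite(prev_obj) and prev_obj - obj <= tol * max(obj, 1e-30):
            converged = True
            break
        prev_obj = obj
    if not converged and max_iter > 1:
        logger.warning("masked ALS did not converge after %d iterations "
                       "(last residual %.3e)", max_iter, obj)

    # unit-variance factors, scale absorbed into loadings
    sd = Z.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = Z / sd
    for ct in views:
        W[ct] = W[ct] * sd

    # order factors by total R^2 (computed on the scaled blocks)
    totals = np.zeros(K)
    denom = sum(float((Xobs[ct][:, obs_cols[ct]] ** 2).sum()) for ct in views)
    for k in range(K):
        expl = 0.0
        for ct in views:
            cols = obs_cols[ct]
            R = Xobs[ct][:, cols] - np.outer(W[ct][:, k], Z[cols, k])
            expl += float((Xobs[ct][:, cols] ** 2).sum() - (R ** 2).sum())
        totals[k] = expl / denom
    order = np.argsort(-totals)
    Z = Z[:, order]
    for ct in views:
        W[ct] = W[ct][:, order]

    # sign convention: positive association with HF when labels exist
    labels = (dataset.metadata.loc[samples, "disease"]
              if "disease" in dataset.metadata.columns else None)
    for k in range(K):
        flip = False
        if labels is not None and labels.nunique() == 2:
            hf = (labels == "HF").to_numpy().astype(float)
            r = np.corrcoef(Z[:, k], hf)[0, 1]
            flip = bool(np.isfinite(r) and r < 0)
        else:
            wcat = np.concatenate([W[ct][:, k] for ct in views])
            flip = wcat[np.argmax(np.abs(wcat))] < 0
        if flip:
            Z[:, k] = -Z[:, k]
            for ct in views:
                W[ct][:, k] = -W[ct][:, k]

    names = [f"MCP{k + 1}" for k in range(K)]
    loadings = {ct: pd.DataFrame(W[ct] / scales[ct],
                                 index=dataset.views[ct].index, columns=names)
                for ct in views}
    scores = pd.DataFrame(Z, index=samples, columns=names)
    model = MCPModel(loadings=loadings, scores=scores, r2=pd.DataFrame(),
                     groups=dataset.groups.copy(), centers=centers,
                     view_scale={ct: scales[ct] for ct in views},
                     converged=converged, n_iter=n_iter)
    model.r2 = variance_explained(model, dataset)
    return model


def variance_explained(model: MCPModel, dataset: MultiViewDataset) -> pd.DataFrame:
    """Per-view, per-factor R^2 on group-centered data (plus view totals)."""
    blocks, masks, _, scales, _, samples = _prepare_matrices(dataset)
    out = {}
    Z = model.scores.loc[samples].to_numpy()
    for ct, X in blocks.items():
        cols = np.flatnonzero(masks[ct])
        Xo = np.nan_to_num(X, nan=0.0)[:, cols]
        W = model.loadings[ct].to_numpy() * scales[ct]
        ss = float((Xo ** 2).sum())
        row = {}
        for k, name in enumerate(model.factor_names()):
            R = Xo - np.outer(W[:, k], Z[cols, k])
            row[name] = max(0.0, 1.0 - float((R ** 2).sum()) / ss) if ss else 0.0
        R_all = Xo - W @ Z[cols].T
        row["total"] = max(0.0, 1.0 - float((R_all ** 2).sum()) / ss) if ss else 0.0
        out[ct] = row
    return pd.DataFrame(out).T


def associate_covariates(model: MCPModel, metadata: pd.DataFrame,
                         covariates: list, use_lmm: bool = False) -> pd.DataFrame:
    """Associate factor scores with clinical covariates.

    Categorical covariates: one-way ANOVA p and R^2 (between-group SS
    fraction); continuous: simple linear regression.  ``use_lmm`` adds a
    study random intercept (Wald p of the covariate effect).  BH across
    all tests.
    """
    meta = metadata.loc[model.scores.index]
    rows = []
    for cov in covariates:
        x = meta[cov]
        if x.nunique(dropna=True) < 2:
            raise ValueError(f"covariate {cov!r} is constant")
        categorical = (x.dtype == object or str(x.dtype) == "category"
                       or x.nunique() <= 3)
        for k in model.scores.columns:
            y = model.scores[k]
            ok = x.notna()
            yv, xv = y[ok], x[ok]
            if use_lmm and not categorical:
                X = np.column_stack([np.ones(ok.sum()),
                                     xv.to_numpy(dtype=float)])
                res = fit_random_intercept(yv.to_numpy(), X,
                                           model.groups.loc[ok.index[ok]])
                p, r2 = res.pvalues[1], res.r2_marginal
            elif categorical:
                parts = [yv[xv == lv].to_numpy() for lv in xv.unique()]
                p = stats.f_oneway(*parts).pvalue
                grand = yv.mean()
                ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in parts)
                ss_t = float(((yv - grand) ** 2).sum())
                r2 = ss_b / ss_t if ss_t else 0.0
            else:
                lr = stats.linregress(xv.to_numpy(dtype=float), yv.to_numpy())
                p, r2 = lr.pvalue, lr.rvalue ** 2
            rows.append({"factor": k, "covariate": cov, "p": p, "r2": r2})
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"])
    return out


def covariate_total_r2(assoc: pd.DataFrame, covariate: str,
                       alpha: float = 0.05) -> float:
    """Total explained variance for a covariate: sum of R^2 over the
    factors significantly associated with it (BH-adjusted p <= alpha)."""
    sub = assoc[(assoc["covariate"] == covariate) & (assoc["adj_p"] <= alpha)]
    return float(sub["r2"].sum())


def de_interaction(views: dict, metadata: pd.DataFrame, covariate: str,
                   mode: str = "interaction",
                   reference_etiology: str = "DCM") -> dict:
    """Per-gene mixed-model interaction / etiology contrasts per view.

    ``interaction`` mode fits ``expr ~ HF * covariate + (1|study)`` and
    reports the interaction coefficient; ``etiology`` mode restricts to
    HF samples and contrasts etiologies against ``reference_etiology``.
    Returns view -> per-gene result table (BH within view).
    """
    results = {}
    for ct, mat in views.items():
        meta = metadata.loc[mat.columns]
        study = meta["study"].to_numpy()
        if mode == "interaction":
            hf = (meta["disease"] == "HF").to_numpy(dtype=float)
            x = meta[covariate]
            xv = (pd.get_dummies(x, drop_first=True).iloc[:, 0].to_numpy(dtype=float)
                  if x.dtype == object else x.to_numpy(dtype=float))
            if np.std(xv[hf == 1]) == 0 or np.std(xv[hf == 0]) == 0:
                raise ValueError(f"covariate {covariate!r} constant within a "
                                 "disease group: interaction is confounded")
            X = np.column_stack([np.ones(len(hf)), hf, xv, hf * xv])
            coef_idx, coef_name = 3, f"HF:{covariate}"
        elif mode == "etiology":
            keep = (meta["disease"] == "HF").to_numpy()
            mat = mat.loc[:, keep]
            meta = meta.loc[keep]
            study = meta["study"].to_numpy()
            levels = [lv for lv in meta["etiology"].unique()
                      if lv != reference_etiology]
            if not levels:
                raise ValueError("no non-reference etiology levels")
            dummies = np.column_stack(
                [(meta["etiology"] == lv).to_numpy(dtype=float) for lv in levels])
            X = np.column_stack([np.ones(len(meta)), dummies])
            coef_idx, coef_name = 1, f"{levels[0]}_vs_{reference_etiology}"
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows = []
        Y = mat.to_numpy()
        for gi, gene in enumerate(mat.index):
            res = fit_random_intercept(Y[gi], X, study)
            rows.append({"gene": gene, "coef": res.beta[coef_idx],
                         "se": res.se[coef_idx], "p": res.pvalues[coef_idx]})
        tab = pd.DataFrame(rows).set_index("gene")
        tab["adj_p"] = bh_adjust(tab["p"])
        tab.attrs["coefficient"] = coef_name
        results[ct] = tab
    return results
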