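"""Normalization, differential expression and consensus meta-analysis.

Counts are normalized by the trimmed mean of M-values (TMM) and turned
into log2 counts-per-million.  Case-control and one-vs-rest contrasts use
per-gene linear models with empirical-Bayes variance moderation: the
posterior variance is ``(d0*s0^2 + d*s^2) / (d0 + d)`` with ``d0`` prior
degrees of freedom and ``s0^2`` the mean residual variance, and the
moderated t is referred to a t distribution with ``d0 + d`` df.  Per-study
results are combined across studies with Fisher's combined probability
test (-2 * sum(log p), chi-square with 2k df for a gene measured in k
studies), and marker-set agreement between studies is quantified with
Jaccard indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "DiseaseSignature",
    "ConsensusRanking",
    "tmm_factors",
    "logcpm",
    "differential_expression",
    "detect_markers",
    "consensus_markers",
    "fisher_meta",
    "jaccard_agreement",
]

P_FLOOR = 1e-300  # clip for zero p-values before Fisher combination


@dataclass
class DiseaseSignature:
    """Per-gene statistics of one case-control (or one-vs-rest) contrast."""

    table: pd.DataFrame  # columns: logFC, t, p, adj_p (index: gene)
    study: str = ""
    celltype: str = "bulk"
    contrast: str = "HF_vs_NF"

    def top_genes(self, n: int = 500) -> pd.DataFrame:
        """Top-n genes by p-value; ties broken by |t| desc, then gene id."""
        t = self.table
        order = np.lexsort((t.index, -t["t"].abs().to_numpy(),
                            t["p"].to_numpy()))
        return t.iloc[order[:n]]

    def up_down_sets(self, n: int = 500):
        top = self.top_genes(n)
        return (set(top.index[top["logFC"] > 0]), set(top.index[top["logFC"] < 0]))


@dataclass
class ConsensusRanking:
    table: pd.DataFrame  # fisher_stat, df, n_studies, p, adj_p, mean_logfc, rank
    min_studies: int = 3


def tmm_factors(counts: pd.DataFrame, logratio_trim: float = 0.30,
                sum_trim: float = 0.05) -> pd.Series:
    """TMM normalization factors (multiply library sizes; geo-mean 1).

    Reference column: the sample whose 75th count-share percentile is
    closest to the mean across samples.  For each sample, M (log2 ratio)
    and A (log2 abundance) values vs the reference are double-trimmed
    (30% on M, 5% on A, both tails) and the factor is 2 to the
    precision-weighted mean of the surviving M values.
    """
    X = counts.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (X < 0).any():
        raise ValueError("negative counts")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero sample")
    f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(X.shape[1])
    xr, lr = X[:, ref], lib[ref]
    for j in range(X.shape[1]):
        if j == ref:
            continue
        xj, lj = X[:, j], lib[j]
        fin = (xj > 0) & (xr > 0)
        if fin.sum() == 0:
            continue
        pj, pr = xj[fin] / lj, xr[fin] / lr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        # precision weights: inverse of the delta-method variance of M
        v = (lj - xj[fin]) / (lj * xj[fin]) + (lr - xr[fin]) / (lr * xr[fin])
        w = 1.0 / v
        n = fin.sum()
        loL = np.floor(n * logratio_trim) + 1
        hiL = n + 1 - loL
        loS = np.floor(n * sum_trim) + 1
        hiS = n + 1 - loS
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loL) & (rM <= hiL) & (rA >= loS) & (rA <= hiS)
        if keep.sum() == 0 or w[keep].sum() == 0:
            continue
        f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
        if np.isfinite(f):
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def logcpm(counts: pd.DataFrame, factors: pd.Series | None = None,
           prior_count: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / (libsize * factor) * 1e6).
    """
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    f = np.ones(X.shape[1]) if factors is None else factors.reindex(counts.columns).to_numpy()
    eff = lib * f
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    out = np.log2((X + prior_count) / eff[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def differential_expression(logexpr: pd.DataFrame, group_labels,
                            covariates: pd.DataFrame | None = None,
                            positive_class=None, prior_df: float = 4.0,
                            study: str = "", celltype: str = "bulk") -> DiseaseSignature:
    """Per-gene moderated-t contrast between two groups.

    Fits gene-wise linear models with an intercept, the group indicator
    and optional covariate columns; moderates residual variances toward
    their mean with ``prior_df`` prior df.  ``prior_df = 0`` recovers the
    ordinary (pooled-variance) t-test.
    """
    y = logexpr.to_numpy(dtype=float)
    groups = np.asarray(group_labels)
    classes = pd.unique(groups)
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    if positive_class is None:
        positive_class = "HF" if "HF" in classes else classes[0]
    ind = (groups == positive_class).astype(float)
    if ind.sum() < 2 or (1 - ind).sum() < 2:
        raise ValueError("need >= 2 samples per group")

    X = np.column_stack([np.ones_like(ind), ind])
    if covariates is not None:
        C = pd.get_dummies(covariates, drop_first=True).to_numpy(dtype=float)
        X = np.column_stack([X, C])
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("confounded design: group collinear with covariates")

    XtX_inv = np.linalg.inv(X.T @ X)
    B = y @ X @ XtX_inv.T            # genes x p
    resid = y - B @ X.T
    d = n - p
    s2 = (resid ** 2).sum(axis=1) / d
    s0_2 = float(np.mean(s2))
    post_s2 = (prior_df * s0_2 + d * s2) / (prior_df + d)
    c = XtX_inv[1, 1]
    se = np.sqrt(post_s2 * c)
    beta = B[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    df_total = prior_df + d
    pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {"logFC": beta, "t": t, "p": pvals, "adj_p": bh_adjust(pvals)},
        index=logexpr.index,
    )
    return DiseaseSignature(table=table, study=study, celltype=celltype,
                            contrast=f"{positive_class}_vs_rest")


def detect_markers(study_views: dict, lfc_threshold: float = 2.0,
                   fdr_threshold: float = 0.01, prior_df: float = 4.0):
    """One-vs-rest cell-type markers within one study.

    All of the study's pseudobulk profiles are pooled, TMM + log-CPM
    normalized, and each cell type is contrasted against the rest.  Genes
    with log2 fold change > 2 and BH FDR < 0.01 are markers.

    ``study_views``: cell type -> genes x samples count matrix.
    Returns ``(marker_sets, signatures)``.
    """
    if len(study_views) < 2:
        raise ValueError("marker detection needs >= 2 cell types")
    celltypes = sorted(study_views)
    mats, labels = [], []
    for ct in celltypes:
        m = study_views[ct].copy()
        m.columns = [f"{ct}|{c}" for c in m.columns]
        mats.append(m)
        labels.extend([ct] * m.shape[1])
    combined = pd.concat(mats, axis=1)
    combined = combined.fillna(0.0)
    expr = logcpm(combined, tmm_factors(combined))
    labels = np.asarray(labels)
    marker_sets, signatures = {}, {}
    for ct in celltypes:
        sig = differential_expression(
            expr, np.where(labels == ct, ct, "rest"), positive_class=ct,
            prior_df=prior_df, celltype=ct)
        tab = sig.table
        marker_sets[ct] = set(tab.index[(tab["logFC"] > lfc_threshold)
                                        & (tab["adj_p"] < fdr_threshold)])
        signatures[ct] = sig
    return marker_sets, signatures


def consensus_markers(views_by_study: dict, min_studies: int = 3,
                      lfc_threshold: float = 2.0,
                      fdr_threshold: float = 0.01):
    """Consensus cell-type markers across studies.

    Runs the one-vs-rest contrast per study, combines the per-study FDRs
    of genes measured in at least ``min_studies`` studies with Fisher's
    method, and calls a gene a consensus marker of a type when its
    combined BH-adjusted p clears ``fdr_threshold`` and its mean log2
    fold change across studies exceeds ``lfc_threshold``.

    ``views_by_study``: study -> (cell type -> genes x samples counts).
    Returns ``(marker_sets, rankings)`` with one consensus ranking per
    cell type.
    """
    per_study: dict = {}
    celltypes: set = set()
    for study, sv in views_by_study.items():
        if len(sv) < 2:
            continue
        sets, sigs = detect_markers(sv, lfc_threshold, fdr_threshold)
        per_study[study] = sigs
        celltypes |= set(sigs)
    if len(per_study) < min_studies:
        raise ValueError(
            f"need >= {min_studies} studies with >= 2 cell types each")
    marker_sets, rankings = {}, {}
    for ct in sorted(celltypes):
        p_cols, lfc_cols = {}, {}
        for study, sigs in per_study.items():
            if ct in sigs:
                p_cols[study] = sigs[ct].table["adj_p"]
                lfc_cols[study] = sigs[ct].table["logFC"]
        P = pd.DataFrame(p_cols)
        L = pd.DataFrame(lfc_cols)
        ranking = fisher_meta(P, min_studies=min_studies, logfc_matrix=L)
        tab = ranking.table
        marker_sets[ct] = set(tab.index[(tab["adj_p"] < fdr_threshold)
                                        & (tab["mean_logfc"] > lfc_threshold)])
        rankings[ct] = ranking
    return marker_sets, rankings


def fisher_meta(p_matrix: pd.DataFrame, min_studies: int = 3,
                logfc_matrix: pd.DataFrame | None = None) -> ConsensusRanking:
    """Fisher's combined probability test across studies.

    Genes measured (non-NaN p) in fewer than ``min_studies`` studies are
    excluded; the statistic is -2 * sum(ln p) with 2k degrees of freedom
    for k studies; BH adjustment is applied across the retained genes.
    """
    P = p_matrix.to_numpy(dtype=float)
    if np.nanmin(P) < 0 or np.nanmax(P) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    if (P == 0).any():
        warnings.warn("p = 0 clipped to 1e-300 before Fisher combination",
                      RuntimeWarning, stacklevel=2)
        P = np.where(P == 0, P_FLOOR, P)
    measured = ~np.isnan(P)
    k = measured.sum(axis=1)
    stat = np.where(measured, -2.0 * np.log(np.where(measured, P, 1.0)), 0.0).sum(axis=1)
    keep = k >= min_studies
    df = 2 * k
    combined = np.full(len(P), np.nan)
    combined[keep] = stats.chi2.sf(stat[keep], df[keep])
    mean_lfc = (np.nanmean(logfc_matrix.to_numpy(), axis=1)
                if logfc_matrix is not None else np.full(len(P), np.nan))
    table = pd.DataFrame(
        {"fisher_stat": stat, "df": df, "n_studies": k, "p": combined,
         "adj_p": np.nan, "mean_logfc": mean_lfc},
        index=p_matrix.index,
    ).loc[keep]
    table["adj_p"] = bh_adjust(table["p"])
    order = np.lexsort((table.index, -np.abs(table["mean_logfc"].fillna(0.0)),
                        table["adj_p"]))
    table = table.iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    return ConsensusRanking(table=table, min_studies=min_studies)


def jaccard_agreement(marker_sets: dict) -> pd.DataFrame:
    """Pairwise Jaccard index |A & B| / |A | B| between named gene sets."""
    names = list(marker_sets)
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            A, B = set(marker_sets[a]), set(marker_sets[b])
            union = A | B
            if not union:
                warnings.warn(f"both {a} and {b} empty: Jaccard set to 0",
                              RuntimeWarning, stacklevel=2)
                jac = 0.0
            else:
                jac = len(A & B) / len(union)
            out.iloc[i, j] = out.iloc[j, i] = jac
    return out
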