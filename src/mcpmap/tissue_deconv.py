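"""Bulk tracing of multicellular programs, deregulation annotation, and
marker-aware deconvolution benchmarking.

The consensus bulk disease signature is annotated gene-by-gene with the
deregulation mechanism it is compatible with: *compositional* (the gene
marks a cell type whose abundance shifts; score = mean marker log-fold
change x mean compositional t of the marking type, summed over types),
*molecular* (the gene's mean factor loading across cell-type views), or
both; a gene whose bulk direction agrees with neither score — or that
was never modeled in single-cell data — is *unknown*.  Deconvolution of
bulk mixtures uses non-negative least squares against replicate TPM
signature matrices built from a healthy reference and restricted to
selectable marker subsets, benchmarked with per-study RMSE/Pearson and
per-change-class F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

from ._stats import auroc, zscore_rows
from .enrichment_core import WEIGHT_FLOOR, ulm_score_matrix

__all__ = [
    "DeregulationAnnotation",
    "bulk_mcp_enrichment",
    "compositional_score",
    "molecular_score",
    "annotate_deregulation",
    "build_signature_matrix",
    "deconvolve",
    "benchmark_deconv",
]

CLASSES = ("compositional", "molecular", "compositional_and_molecular", "unknown")


@dataclass
class DeregulationAnnotation:
    table: pd.DataFrame   # bulk_direction, comp_score, mol_score, label

    @property
    def fractions(self) -> pd.Series:
        f = self.table["label"].value_counts(normalize=True)
        return f.reindex(CLASSES, fill_value=0.0)


def bulk_mcp_enrichment(bulk_by_study: dict, model, factor: str,
                        labels_by_study: dict | None = None,
                        min_abs: float = WEIGHT_FLOOR,
                        min_overlap: int = 25):
    """Enrich each cell type's program signature in bulk studies.

    Gene expression of each study is centered and scaled across samples
    (so study-level offsets cancel), then scored with each view's factor
    loadings.  Returns ``(scores, aurocs)``: scores indexed by (study,
    sample) with one column per cell type; aurocs per (study, cell type)
    when HF/NF labels are provided.
    """
    score_rows, auroc_rows = [], []
    for study, bulk in bulk_by_study.items():
        Z = pd.DataFrame(zscore_rows(bulk.to_numpy()), index=bulk.index,
                         columns=bulk.columns)
        per_ct = {}
        for ct, W in model.loadings.items():
            w = W[factor]
            n_over = int((w.abs() >= min_abs)
                         .loc[w.index.intersection(Z.index)].sum())
            if n_over < min_overlap:
                raise ValueError(
                    f"signature overlap {n_over} < {min_overlap} for view {ct}")
            per_ct[ct] = ulm_score_matrix(Z, w, min_abs=min_abs)
        sc = pd.DataFrame(per_ct)
        sc.index = pd.MultiIndex.from_product([[study], sc.index],
                                              names=["study", "sample"])
        score_rows.append(sc)
        if labels_by_study is not None:
            lab = np.asarray(labels_by_study[study])
            for ct in per_ct:
                auroc_rows.append({
                    "study": study, "celltype": ct,
                    "auroc": auroc(per_ct[ct].to_numpy(), lab, "HF"),
                })
    scores = pd.concat(score_rows)
    aurocs = pd.DataFrame(auroc_rows) if auroc_rows else None
    return scores, aurocs


def compositional_score(marker_logfc: pd.DataFrame,
                        comp_t: pd.Series) -> pd.Series:
    """Per-gene compositional deregulation score.

    ``marker_logfc``: genes x cell types mean marker log-fold change
    (NaN where the gene does not mark the type); ``comp_t``: mean
    compositional t per cell type.  score_g = sum over marking types of
    logFC * t; genes marking no type are absent from the result.
    """
    vals = {}
    for g in marker_logfc.index:
        row = marker_logfc.loc[g]
        total, seen = 0.0, False
        for ct, lfc in row.items():
            if pd.isna(lfc) or ct not in comp_t.index or pd.isna(comp_t[ct]):
                continue
            total += float(lfc) * float(comp_t[ct])
            seen = True
        if seen:
            vals[g] = total
    return pd.Series(vals, name="comp_score")


def molecular_score(model, factor: str) -> pd.Series:
    """Mean factor loading across the cell-type views modeling each gene."""
    frames = [W[factor].rename(ct) for ct, W in model.loadings.items()]
    mat = pd.concat(frames, axis=1)
    return mat.mean(axis=1, skipna=True).rename("mol_score")


def annotate_deregulation(bulk_consensus: pd.DataFrame,
                          comp_scores: pd.Series,
                          mol_scores: pd.Series,
                          alpha: float = 0.05) -> DeregulationAnnotation:
    """Sign-agreement annotation of the significant consensus genes.

    ``bulk_consensus`` needs columns ``mean_logfc`` and ``adj_p``; only
    genes with adj_p < ``alpha`` are annotated.  Agreement of the bulk
    direction with the compositional score only -> compositional; with
    the molecular score only -> molecular; with both -> compositional_
    and_molecular; with neither (or no single-cell evidence) -> unknown.
    """
    sig = bulk_consensus[bulk_consensus["adj_p"] < alpha]
    rows = []
    for g in sig.index:
        direction = np.sign(sig.loc[g, "mean_logfc"])
        cs = comp_scores.get(g, np.nan)
        ms = mol_scores.get(g, np.nan)
        comp_ok = (not pd.isna(cs)) and np.sign(cs) == direction and cs != 0
        mol_ok = (not pd.isna(ms)) and np.sign(ms) == direction and ms != 0
        if comp_ok and mol_ok:
            label = "compositional_and_molecular"
        elif comp_ok:
            label = "compositional"
        elif mol_ok:
            label = "molecular"
        else:
            label = "unknown"
        rows.append({"gene": g, "bulk_direction": direction,
                     "comp_score": cs, "mol_score": ms, "label": label})
    cols = ["gene", "bulk_direction", "comp_score", "mol_score", "label"]
    table = pd.DataFrame(rows, columns=cols).set_index("gene")
    return DeregulationAnnotation(table)


def build_signature_matrix(reference_views: dict, marker_subset,
                           n_replicates: int = 3, sample_frac: float = 0.30,
                           seed: int = 0) -> list:
    """Replicate TPM signature matrices from a healthy reference.

    For each replicate, 30% of the reference samples per view are drawn
    without replacement, averaged, scaled to TPM (columns sum to 1e6)
    and restricted to ``marker_subset``.  Returns a list of genes x
    cell-types matrices (predictions from the replicates are averaged
    after deconvolution).
    """
    rng = np.random.default_rng(seed)
    subset = set(marker_subset)
    out = []
    for _ in range(n_replicates):
        cols = {}
        for ct, mat in reference_views.items():
            n = mat.shape[1]
            take = max(1, int(round(sample_frac * n)))
            chosen = rng.choice(mat.columns, size=take, replace=False)
            prof = mat[chosen].mean(axis=1).clip(lower=0.0)
            tot = prof.sum()
            if tot <= 0:
                raise ValueError(f"empty reference profile for {ct}")
            cols[ct] = prof / tot * 1e6
        sig = pd.DataFrame(cols)
        keep = [g for g in sig.index if g in subset]
        if not keep:
            raise ValueError("marker subset empty after intersection")
        sig = sig.loc[keep]
        if (sig.sum(axis=1) == 0).all():
            raise ValueError("marker subset empty for every cell type")
        out.append(sig)
    return out


def deconvolve(bulk: pd.DataFrame, signatures) -> pd.DataFrame:
    """Non-negative least-squares deconvolution, replicate-averaged.

    Each bulk sample is regressed on the signature matrix over shared
    genes; coefficients are clipped at zero by construction and
    normalized to the simplex.  ``signatures`` may be one matrix or a
    list of replicates whose predictions are averaged.
    """
    if isinstance(signatures, pd.DataFrame):
        signatures = [signatures]
    preds = []
    for sig in signatures:
        shared = [g for g in sig.index if g in bulk.index]
        if len(shared) < 25:
            raise ValueError(f"only {len(shared)} shared genes (< 25)")
        A = sig.loc[shared].to_numpy(dtype=float)
        B = bulk.loc[shared].to_numpy(dtype=float)
        props = np.zeros((bulk.shape[1], sig.shape[1]))
        for j in range(B.shape[1]):
            coef, _ = nnls(A, B[:, j])
            tot = coef.sum()
            if tot <= 0:
                warnings.warn("all-zero NNLS coefficients: uniform fallback",
                              RuntimeWarning, stacklevel=2)
                coef = np.ones_like(coef)
                tot = coef.sum()
            props[j] = coef / tot
        preds.append(pd.DataFrame(props, index=bulk.columns,
                                  columns=sig.columns))
    avg = sum(preds) / len(preds)
    return avg.div(avg.sum(axis=1), axis=0)


def benchmark_deconv(estimates: pd.DataFrame, truth: pd.DataFrame,
                     study_labels, disease_labels=None,
                     alpha: float = 0.05):
    """Per-study RMSE and Pearson r, plus change-class F1 when labels given.

    Change classes (increase / decrease / no_change) are assigned per
    (study, cell type) by a t-test (p < 0.05) of HF vs NF proportions,
    separately on the truth and on the estimates, and compared with
    per-class F1 scores.
    """
    celltypes = [ct for ct in truth.columns if ct in estimates.columns]
    est = estimates[celltypes].loc[truth.index]
    study_labels = pd.Series(np.asarray(study_labels), index=truth.index)
    rows = []
    for study in study_labels.unique():
        idx = study_labels.index[study_labels == study]
        if len(idx) < 3:
            raise ValueError(f"study {study}: fewer than 3 samples")
        e = est.loc[idx].to_numpy().ravel()
        t = truth.loc[idx, celltypes].to_numpy().ravel()
        rmse = float(np.sqrt(np.mean((e - t) ** 2)))
        r = float(stats.pearsonr(e, t)[0])
        rows.append({"study": study, "rmse": rmse, "pearson": r})
    metrics = pd.DataFrame(rows).set_index("study")
    f1 = None
    if disease_labels is not None:
        disease_labels = pd.Series(np.asarray(disease_labels), index=truth.index)
        def classify(tab):
            out = []
            for study in study_labels.unique():
                idx = study_labels.index[study_labels == study]
                hf = idx[disease_labels.loc[idx] == "HF"]
                nf = idx[disease_labels.loc[idx] == "NF"]
                for ct in celltypes:
                    tt, p = stats.ttest_ind(tab.loc[hf, ct], tab.loc[nf, ct])
                    label = ("increase" if (p < alpha and tt > 0)
                             else "decrease" if (p < alpha and tt < 0)
                             else "no_change")
                    out.append(label)
            return np.array(out)
        y_true = classify(truth[celltypes])
        y_pred = classify(est)
        from sklearn.metrics import f1_score
        labels = ["increase", "decrease", "no_change"]
        f1 = pd.Series(
            f1_score(y_true, y_pred, labels=labels, average=None,
                     zero_division=0),
            index=labels, name="f1")
    return metrics, f1
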