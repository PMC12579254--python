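"""Compositional analysis of cell-type proportions.

Proportions live on the simplex, so disease effects are tested after a
centered log-ratio (clr) transform: ``clr_k = ln(p_k / g(p))`` with
``g(p)`` the geometric mean of the sample's proportions.  Per-study
signatures are Welch t-tests on clr values (HF vs NF); a transferable
compositional disease score combines a test sample's scaled clr values
with a reference study's t-vector; and cross-study composition changes
are estimated with a random-intercept (study) linear mixed model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from ._stats import auroc, bh_adjust, zscore_rows
from .lmm import fit_random_intercept

__all__ = [
    "clr_transform",
    "clr_inverse",
    "compositional_signature",
    "compositional_disease_score",
    "lmm_composition",
    "cluster_compositions",
]


def clr_transform(props: pd.DataFrame, pseudo: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform of row-stochastic proportions.

    Zeros are replaced multiplicatively with ``pseudo`` (default
    0.5 / n_parts per affected row) before taking logs; rows are then
    re-closed to sum 1.  Output rows sum to 0.
    """
    P = props.to_numpy(dtype=float)
    if (P < 0).any():
        raise ValueError("negative proportions")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows must lie on the simplex (sum to 1)")
    if (P == 0).any():
        eps = pseudo if pseudo is not None else 0.5 / P.shape[1]
        P = np.where(P == 0, eps, P)
        P = P / P.sum(axis=1, keepdims=True)
    L = np.log(P)
    clr = L - L.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=props.index, columns=props.columns)


def clr_inverse(clr: pd.DataFrame) -> pd.DataFrame:
    """Softmax inverse: recovers proportions up to closure."""
    E = np.exp(clr.to_numpy(dtype=float))
    return pd.DataFrame(E / E.sum(axis=1, keepdims=True),
                        index=clr.index, columns=clr.columns)


def compositional_signature(clr: pd.DataFrame, labels,
                            positive_class: str = "HF") -> pd.DataFrame:
    """Welch t-test of clr values per cell type, HF vs NF, BH-adjusted."""
    labels = np.asarray(labels)
    pos = labels == positive_class
    if pos.sum() < 2 or (~pos).sum() < 2:
        raise ValueError("need >= 2 samples per group")
    A = clr.to_numpy()[pos]
    B = clr.to_numpy()[~pos]
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    out = pd.DataFrame({"t": t, "p": p, "adj_p": bh_adjust(p),
                        "mean_diff": A.mean(axis=0) - B.mean(axis=0)},
                       index=clr.columns)
    return out


def compositional_disease_score(test_clr: pd.DataFrame, ref_t: pd.Series,
                                labels=None, positive_class: str = "HF"):
    """Transferable compositional disease score.

    Per-cell-type clr values are z-scored across the test study's samples
    and linearly combined with the reference t-vector.  Returns a
    ``(scores, auroc)`` pair (auroc None without labels).
    """
    shared = [ct for ct in ref_t.index if ct in test_clr.columns]
    if not shared:
        raise ValueError("no shared cell types between test and reference")
    Z = zscore_rows(test_clr[shared].to_numpy().T)  # celltypes x samples
    scores = pd.Series(Z.T @ ref_t.loc[shared].to_numpy(),
                       index=test_clr.index, name="comp_disease_score")
    a = None
    if labels is not None:
        a = auroc(scores.to_numpy(), np.asarray(labels), positive_class)
    return scores, a


def lmm_composition(clr: pd.DataFrame, disease, study,
                    positive_class: str = "HF") -> pd.DataFrame:
    """Cross-study composition change per cell type via mixed models.

    Fits ``clr ~ disease + (1|study)`` by profiled REML for each cell
    type; reports the disease fixed effect, Wald p (BH across cell
    types) and the proportion of variance attributed to study.  With a
    single study, falls back to a fixed-effect Welch t-test.
    """
    disease = np.asarray(disease)
    study = np.asarray(study)
    ind = (disease == positive_class).astype(float)
    if len(np.unique(study)) < 2:
        warnings.warn("single study: falling back to fixed-effects t-test",
                      RuntimeWarning, stacklevel=2)
        sig = compositional_signature(clr, disease, positive_class)
        sig = sig.rename(columns={"mean_diff": "estimate"})
        sig["study_var_prop"] = 0.0
        return sig[["estimate", "t", "p", "adj_p", "study_var_prop"]]
    X = np.column_stack([np.ones_like(ind), ind])
    rows = []
    for ct in clr.columns:
        res = fit_random_intercept(clr[ct].to_numpy(), X, study)
        rows.append({"celltype": ct, "estimate": res.beta[1],
                     "se": res.se[1], "p": res.pvalues[1],
                     "study_var_prop": res.study_variance_proportion})
    out = pd.DataFrame(rows).set_index("celltype")
    out["adj_p"] = bh_adjust(out["p"])
    return out


def cluster_compositions(props: pd.DataFrame, n_clusters: int = 2):
    """Average-linkage hierarchical clustering on Euclidean distances.

    Returns ``(linkage_matrix, cluster_labels)``.
    """
    Z = average(pdist(props.to_numpy(), metric="euclidean"))
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=props.index, name="cluster")
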