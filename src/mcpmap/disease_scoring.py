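"""Transferable disease scores and cross-study classification.

A reference study's differential-expression t-vector defines a disease
pattern; a test sample's score is the dot product of its per-gene
z-scored expression with the reference t-values over the reference's
top-n genes.  Transferability is measured with the AUROC of the scores
against the test study's HF/NF labels.  Directional enrichment of a
reference's up/down gene sets in another study's gene ranking uses the
weighted Kolmogorov-Smirnov running-sum statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from ._stats import auroc, zscore_rows
from .normalization_de import DiseaseSignature

__all__ = [
    "ScoreResult",
    "disease_score",
    "auroc",
    "directional_enrichment",
    "silhouette",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreResult:
    scores: pd.Series          # per test sample
    reference: str
    n_genes_used: int
    auroc: float | None = None


def disease_score(test_logexpr: pd.DataFrame, ref_signature: DiseaseSignature,
                  top_n: int = 500, labels=None, positive_class: str = "HF",
                  min_overlap: int = 50) -> ScoreResult:
    """Score test samples against a reference disease signature.

    Genes are z-scored across the test study's samples; each sample's
    score is ``sum_g z_{g,i} * t_g`` over the reference's top-n genes by
    p-value.  Higher scores are more HF-like (assuming the reference
    contrast is HF vs NF).  Reference genes absent from the test matrix
    are dropped; the overlap is logged.
    """
    top = ref_signature.top_genes(top_n)
    shared = [g for g in top.index if g in test_logexpr.index]
    if len(shared) < min_overlap:
        raise ValueError(
            f"only {len(shared)} reference genes found in the test matrix "
            f"(minimum {min_overlap})")
    logger.info("disease score uses %d/%d reference genes", len(shared), len(top))
    Z = zscore_rows(test_logexpr.loc[shared].to_numpy())
    t = top.loc[shared, "t"].to_numpy()
    scores = pd.Series(Z.T @ t, index=test_logexpr.columns, name="disease_score")
    result = ScoreResult(scores=scores,
                         reference=f"{ref_signature.study}:{ref_signature.contrast}",
                         n_genes_used=len(shared))
    if labels is not None:
        result.auroc = auroc(scores.to_numpy(), np.asarray(labels), positive_class)
    return result


def directional_enrichment(ranking: pd.Series, up_set, down_set,
                           weight_exponent: float = 1.0):
    """Weighted KS enrichment of up/down sets in a gene-level ranking.

    Genes are ranked by the statistic (descending); hits increment the
    running sum proportionally to |statistic|^weight_exponent, misses
    decrement uniformly; the enrichment score is the maximal deviation
    from zero, in [-1, 1].  Returns ``(es_up, es_down)``.
    """
    return (_es(ranking, up_set, weight_exponent),
            _es(ranking, down_set, weight_exponent))


def _es(ranking: pd.Series, gene_set, weight_exponent: float) -> float:
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    r = ranking.sort_values(ascending=False)
    stat = r.to_numpy(dtype=float)
    hit = np.array([g in gene_set for g in r.index])
    if not hit.any():
        raise ValueError("gene set does not overlap the ranking universe")
    w = np.abs(stat) ** weight_exponent
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit statistics are exactly zero: unweighted steps
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    miss = (~hit).astype(float)
    running = np.cumsum(hit_w / denom - miss / max(miss.sum(), 1.0))
    return float(running[np.argmax(np.abs(running))])


def silhouette(dist_matrix: pd.DataFrame, labels) -> pd.DataFrame:
    """Silhouette widths from a precomputed distance matrix.

    Returns a per-sample table (width, label); median widths per label are
    available via ``df.groupby('label')['width'].median()``.  Samples in
    singleton clusters get width 0 by convention.
    """
    D = np.asarray(dist_matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    widths = np.zeros(len(labels))
    multi = counts[counts > 1].index
    if len(multi) >= 2:
        mask = np.isin(labels, multi)
        widths[mask] = silhouette_samples(D[np.ix_(mask, mask)], labels[mask],
                                          metric="precomputed")
    index = (dist_matrix.index if isinstance(dist_matrix, pd.DataFrame)
             else pd.RangeIndex(len(labels)))
    return pd.DataFrame({"width": widths, "label": labels}, index=index)
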