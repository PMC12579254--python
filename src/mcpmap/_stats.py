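"""Small shared statistical helpers used across modules."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "auroc", "zscore_rows", "average_precision"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def auroc(scores, labels, positive_class=1) -> float:
    """Area under the ROC curve via the Mann-Whitney U statistic.

    Uses midranks, so ties contribute 1/2; equivalent to counting
    concordant score pairs between the positive and negative class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def zscore_rows(mat: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Z-score each row across columns; constant rows become 0."""
    mat = np.asarray(mat, dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=ddof, keepdims=True)
    sd[sd == 0] = 1.0
    return (mat - mu) / sd


def average_precision(y_true, y_score) -> float:
    """Step-interpolated area under the precision-recall curve.

    AP = sum_k (R_k - R_{k-1}) * P_k over descending score thresholds.
    """
    y_true = np.asarray(y_true, dtype=bool)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int(y_true.sum())
    if n_pos == 0:
        raise ValueError("no positive examples")
    order = np.argsort(-y_score, kind="mergesort")
    y = y_true[order]
    s = y_score[order]
    tp = np.cumsum(y)
    fp = np.cumsum(~y)
    # collapse tied thresholds: evaluate at the last index of each tie block
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_rec = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_rec) * precision))
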