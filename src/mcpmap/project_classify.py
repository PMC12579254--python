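"""Projection of external cohorts into a fitted MCP space and classifiers.

New cohorts are mapped into a reference model's factor space by
multiplying the Moore-Penrose pseudoinverse of the concatenated gene
loadings with the target's normalized, centered expression, optionally
restricted to a single cell-type view.  Disease classifiers (LDA on all
factor scores; logistic regression on two selected factors) transfer the
HF/NF boundary across cohorts, and cohorts without healthy controls are
standardized gene-wise against a healthy reference atlas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from ._stats import auroc
from .mcp_factor import MCPModel

__all__ = [
    "ProjectionResult",
    "project_samples",
    "standardize_to_reference",
    "train_lda",
    "predict_lda",
    "logistic_boundary",
]

logger = logging.getLogger(__name__)


@dataclass
class ProjectionResult:
    scores: pd.DataFrame        # samples x K projected factor scores
    overlap: dict               # view -> genes used
    restricted_to: str | None = None


def _center_columns(mat: pd.DataFrame, center: str = "target") -> pd.DataFrame:
    if center == "target":
        return mat.sub(mat.mean(axis=1), axis=0)
    if center == "none":
        return mat
    raise ValueError(f"unknown centering mode {center!r}")


def project_samples(model: MCPModel, target_views: dict,
                    restrict_to_view: str | None = None,
                    center: str = "target",
                    min_overlap_frac: float = 0.10) -> ProjectionResult:
    """Project normalized target views into the model's factor space.

    Concatenates the model loadings over the genes shared with the
    target (missing genes are dropped from the loading matrix, not
    zero-filled), applies the training view scaling, and multiplies the
    pseudoinverse of the concatenated loadings with the centered target
    data.  ``restrict_to_view`` zeroes every other view's loadings so
    only one cell type drives the projection.
    """
    views = [ct for ct in model.loadings if ct in target_views]
    if restrict_to_view is not None and restrict_to_view not in model.loadings:
        raise KeyError(f"model has no view {restrict_to_view!r}")
    if not views:
        raise ValueError("no model views present in the target")
    missing = set(model.loadings) - set(views)
    if missing and restrict_to_view is None:
        logger.warning("target misses views %s: projection uses the rest",
                       sorted(missing))

    samples = sorted({c for ct in views for c in target_views[ct].columns})
    W_parts, X_parts, overlap = [], [], {}
    total_model_genes = sum(model.loadings[ct].shape[0] for ct in views)
    for ct in views:
        wv = model.loadings[ct]
        tv = target_views[ct]
        shared = [g for g in wv.index if g in tv.index]
        overlap[ct] = shared
        if not shared:
            continue
        scale = model.view_scale.get(ct, 1.0)
        W = wv.loc[shared].to_numpy() * scale
        if restrict_to_view is not None and ct != restrict_to_view:
            W = np.zeros_like(W)
        Xv = _center_columns(tv.loc[shared], center)
        X = np.zeros((len(shared), len(samples)))
        for j, s in enumerate(samples):
            if s in Xv.columns:
                X[:, j] = Xv[s].to_numpy()
        # data scaled identically to training (per-view 1/sqrt(p_v))
        W_parts.append(W)
        X_parts.append(X * scale)
    n_shared = sum(len(v) for v in overlap.values())
    if n_shared < min_overlap_frac * total_model_genes:
        raise ValueError(
            f"feature overlap {n_shared}/{total_model_genes} below "
            f"{min_overlap_frac:.0%}")
    Wc = np.vstack(W_parts)
    Xc = np.vstack(X_parts)
    Z = np.linalg.pinv(Wc) @ Xc     # K x samples
    scores = pd.DataFrame(Z.T, index=samples, columns=model.factor_names())
    return ProjectionResult(scores=scores, overlap=overlap,
                            restricted_to=restrict_to_view)


def standardize_to_reference(target_views: dict, reference_views: dict) -> dict:
    """Z-score target genes against a healthy reference atlas.

    Per view and gene: ``(x - mean_ref) / sd_ref``.  Reference genes with
    zero variance are dropped (logged).
    """
    out = {}
    for ct, tv in target_views.items():
        if ct not in reference_views:
            continue
        rv = reference_views[ct]
        if rv.shape[1] < 2:
            raise ValueError(f"reference view {ct!r} needs >= 2 samples")
        shared = [g for g in tv.index if g in rv.index]
        if not shared:
            raise ValueError(f"no shared genes in view {ct!r}")
        mu = rv.loc[shared].mean(axis=1)
        sd = rv.loc[shared].std(axis=1, ddof=1)
        ok = sd > 0
        if (~ok).any():
            logger.warning("view %s: %d zero-variance reference genes dropped",
                           ct, int((~ok).sum()))
        genes = sd.index[ok]
        out[ct] = tv.loc[genes].sub(mu[genes], axis=0).div(sd[genes], axis=0)
    return out


def train_lda(scores: pd.DataFrame, labels, positive_class: str = "HF",
              ridge: float = 1e-8) -> LinearDiscriminantAnalysis:
    """Two-class LDA with pooled covariance on factor scores."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("two classes required")
    if len(labels) < scores.shape[1] + 2:
        raise ValueError("need at least K + 2 samples")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=None)
    try:
        clf.fit(scores.to_numpy(), labels)
    except np.linalg.LinAlgError:
        logger.warning("singular pooled covariance: ridge %.1e added", ridge)
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=ridge)
        clf.fit(scores.to_numpy(), labels)
    clf.positive_class_ = positive_class
    return clf


def predict_lda(clf: LinearDiscriminantAnalysis, scores: pd.DataFrame,
                labels=None):
    """Predicted class + positive-class posterior; AUROC if labels given."""
    post = clf.predict_proba(scores.to_numpy())
    pos_idx = list(clf.classes_).index(clf.positive_class_)
    out = pd.DataFrame({
        "predicted": clf.predict(scores.to_numpy()),
        "posterior": post[:, pos_idx],
    }, index=scores.index)
    a = None
    if labels is not None:
        a = auroc(out["posterior"].to_numpy(), np.asarray(labels),
                  clf.positive_class_)
    return out, a


def logistic_boundary(scores_2d: pd.DataFrame, labels,
                      positive_class: str = "HF", max_iter: int = 1000):
    """Logistic HF boundary on two factor scores.

    Near-unpenalized IRLS fit (large C); under perfect separation the
    default penalty keeps the fit finite and a warning is emitted.
    Returns ``(coef dict, boundary function x2(x1), training error)``.
    """
    if scores_2d.shape[1] != 2:
        raise ValueError("exactly two factors required")
    y = (np.asarray(labels) == positive_class).astype(int)
    X = scores_2d.to_numpy()
    clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=max_iter)
    clf.fit(X, y)
    b0 = float(clf.intercept_[0])
    b1, b2 = (float(v) for v in clf.coef_[0])
    if max(abs(b1), abs(b2)) > 1e3:
        logger.warning("near-perfect separation: refitting with penalty")
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=max_iter)
        clf.fit(X, y)
        b0 = float(clf.intercept_[0])
        b1, b2 = (float(v) for v in clf.coef_[0])
    pred = clf.predict(X)
    error = float(np.mean(pred != y))
    coef = {"intercept": b0, scores_2d.columns[0]: b1, scores_2d.columns[1]: b2}

    def boundary(x1):
        if b2 == 0:
            raise ZeroDivisionError("boundary is vertical")
        return (-b0 - b1 * np.asarray(x1)) / b2

    clf.positive_class_ = positive_class
    return coef, boundary, error, clf
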