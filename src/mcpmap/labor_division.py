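"""Division of labor across cell states: specialist vs generalist genes.

Per patient x cell-state pseudobulks are enriched for a program's gene
loadings (sign-flipped so positive associates with disease); enrichment
scores — or per-gene expression — are then modeled as
``y ~ HF + CS + (1|study) + (1|patient)``, and the semi-partial R^2 of
each fixed effect is the drop in marginal (fixed-effect) R^2 when the
model is refitted without it.  Genes are classified with the 0.1
thresholds: specialist (state R^2 > 0.1, disease R^2 < 0.1), generalist
(state < 0.1, disease > 0.1), acquired generalist (both > 0.1), none.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .enrichment_core import WEIGHT_FLOOR, ulm_score, ulm_score_matrix
from .lmm import fit_random_intercepts

__all__ = [
    "state_enrichment",
    "lmm_semipartial",
    "classify_labor",
    "labor_table",
    "state_marker_factor_association",
]

R2_THRESHOLD = 0.1


def state_enrichment(state_pseudobulks: pd.DataFrame, loadings: pd.Series,
                     min_abs: float = WEIGHT_FLOOR,
                     flip_sign: bool = True) -> pd.Series:
    """Program enrichment score per (patient, state) pseudobulk column.

    Loadings are multiplied by -1 by default so that positive scores
    associate with disease when the program's raw orientation points the
    other way; pass ``flip_sign=False`` for factors already oriented
    toward HF.
    """
    w = -loadings if flip_sign else loadings
    return ulm_score_matrix(state_pseudobulks, w, min_abs=min_abs)


def _marginal_r2(y, X, factors) -> tuple:
    res = fit_random_intercepts(y, X, factors)
    return res.r2_marginal, res


def lmm_semipartial(response, hf, cell_state, study, patient) -> pd.Series:
    """Semi-partial R^2 of disease and cell state from a two-intercept LMM.

    Fits ``response ~ HF + CS + (1|study) + (1|patient)`` and refits
    without each fixed effect in turn; the semi-partial R^2 of an effect
    is the (non-negative) drop in marginal R^2.  Also reports Wald
    p-values from the full model.
    """
    y = np.asarray(response, dtype=float)
    hf = np.asarray(hf, dtype=float)
    cs = np.asarray(cell_state)
    states = pd.unique(cs)
    if len(states) < 2:
        raise ValueError("need >= 2 cell states")
    if len(np.unique(hf)) < 2:
        raise ValueError("both disease groups required")
    S = np.column_stack([(cs == s).astype(float) for s in states[1:]])
    X_full = np.column_stack([np.ones(len(y)), hf, S])
    factors = [np.asarray(study), np.asarray(patient)]
    r2_full, res = _marginal_r2(y, X_full, factors)
    r2_no_hf, _ = _marginal_r2(y, np.column_stack([np.ones(len(y)), S]), factors)
    r2_no_cs, _ = _marginal_r2(y, np.column_stack([np.ones(len(y)), hf]), factors)
    sp_hf = max(0.0, r2_full - r2_no_hf)
    sp_cs = max(0.0, r2_full - r2_no_cs)
    p_cs = float(np.min(res.pvalues[2:])) if S.shape[1] else 1.0
    return pd.Series({
        "r2_hf": sp_hf, "r2_cs": sp_cs, "r2_marginal_full": r2_full,
        "p_hf": float(res.pvalues[1]), "p_cs": p_cs,
        "hf_coef": float(res.beta[1]),
    })


def classify_labor(r2_cs: float, r2_hf: float,
                   threshold: float = R2_THRESHOLD) -> str:
    """Threshold rule for division-of-labor classes."""
    if r2_cs > threshold and r2_hf < threshold:
        return "specialist"
    if r2_cs < threshold and r2_hf > threshold:
        return "generalist"
    if r2_cs > threshold and r2_hf > threshold:
        return "acquired_generalist"
    return "none"


def labor_table(expr: pd.DataFrame, meta: pd.DataFrame,
                threshold: float = R2_THRESHOLD) -> pd.DataFrame:
    """Per-gene semi-partial R^2 and labor class.

    ``expr``: genes x (patient, state) columns; ``meta``: per-column
    patient, study, disease (HF/NF) and state annotations.
    """
    meta = meta.loc[expr.columns]
    hf = (meta["disease"] == "HF").to_numpy(dtype=float)
    cs = meta["state"].to_numpy()
    study = meta["study"].to_numpy()
    patient = meta["patient"].to_numpy()
    rows = []
    for gene in expr.index:
        sp = lmm_semipartial(expr.loc[gene].to_numpy(), hf, cs, study, patient)
        sp["label"] = classify_labor(sp["r2_cs"], sp["r2_hf"], threshold)
        sp.name = gene
        rows.append(sp)
    out = pd.DataFrame(rows)
    out["adj_p_hf"] = bh_adjust(out["p_hf"])
    return out


def state_marker_factor_association(state_markers: dict, loadings: pd.Series,
                                    state_comp_changes: pd.Series,
                                    top_n: int = 200,
                                    min_abs: float = 0.0):
    """Enrich each state's top markers in a loading vector and relate the
    per-state enrichment to compositional change.

    ``state_markers``: state -> genes ranked by marker strength (top-n
    used as the marker set, scored with uniform weights restricted to
    the loading vector).  Returns ``(enrichment per state, pearson_r,
    pearson_p)`` where the correlation is between enrichment and the
    planted/observed per-state compositional change.
    """
    if len(state_markers) < 3:
        raise ValueError("need >= 3 states")
    es = {}
    for st, ranked in state_markers.items():
        top = [g for g in ranked[:top_n] if g in loadings.index]
        # score the loading vector against the marker-set indicator
        indicator = pd.Series(0.0, index=loadings.index)
        indicator[top] = 1.0
        es[st] = ulm_score(loadings, indicator, min_abs=-np.inf)
    es = pd.Series(es, name="marker_enrichment")
    shared = [s for s in es.index if s in state_comp_changes.index]
    r, p = stats.pearsonr(es.loc[shared], state_comp_changes.loc[shared])
    return es, float(r), float(p)
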