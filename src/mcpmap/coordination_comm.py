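"""Multicellular coordination networks and ligand-receptor communication.

Per-sample, per-cell-type program signatures (ulm enrichment of each
view's factor loadings in that view's pseudobulk) feed linear mixed
models that predict each cell type's signature from the others' with a
study random intercept; the edge weight from predictor A to target B is
A's coefficient times the overall (conditional) model fit, and edges
below 0.2 are dropped.  Condition-specific (HF vs NF) networks are
compared by the Spearman correlation of their unfiltered importances and
per-cell-type one-sample t-tests of the importance differences.
Ligand-receptor interactions are scored by summing the ligand's and the
receptor's loadings across cell-type pairs (|loading| > 0.1), and ligand
activity on a receiver cell type is prioritized by the corrected AUPR of
a ligand-target prior against the receiver's most extreme loadings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import average_precision, bh_adjust
from .enrichment_core import WEIGHT_FLOOR, ulm_score_matrix
from .lmm import fit_random_intercept

__all__ = [
    "CoordinationNetwork",
    "signature_matrix",
    "coordination_network",
    "compare_networks",
    "lr_scores",
    "prioritize_ligands",
]

logger = logging.getLogger(__name__)

EDGE_WEIGHT_THRESHOLD = 0.2


@dataclass
class CoordinationNetwork:
    """Directed weighted graph over cell types for one condition."""

    edges: pd.DataFrame          # sender, target, coefficient, fit, weight
    condition: str
    fits: dict = field(default_factory=dict)   # target -> model R^2
    importances: pd.DataFrame | None = None    # unfiltered sender x target

    def edge_weight(self, sender: str, target: str) -> float | None:
        m = self.edges[(self.edges["sender"] == sender)
                       & (self.edges["target"] == target)]
        return float(m["weight"].iloc[0]) if len(m) else None


def signature_matrix(model, views: dict, factor: str,
                     min_abs: float = WEIGHT_FLOOR) -> pd.DataFrame:
    """Per-sample, per-cell-type program enrichment scores.

    For each view, the factor's loadings (|w| >= 0.1) are enriched in
    that view's normalized pseudobulk profiles via the univariate linear
    model score.  Samples missing a view get NaN (missing, not zero).
    """
    cols = {}
    for ct, expr in views.items():
        if ct not in model.loadings:
            continue
        w = model.loadings[ct][factor]
        cols[ct] = ulm_score_matrix(expr, w, min_abs=min_abs)
    return pd.DataFrame(cols)


def coordination_network(signatures: pd.DataFrame, study,
                         condition_mask=None, condition: str = "all",
                         weight_threshold: float = EDGE_WEIGHT_THRESHOLD,
                         fit_mode: str = "conditional",
                         absolute: bool = False) -> CoordinationNetwork:
    """Mixed-model coordination network over cell types.

    For each target cell type: ``target ~ sum(predictors) + (1|study)``
    on the condition's samples, predictors standardized so coefficients
    compare across cell types.  Edge weight = coefficient x overall model
    fit (conditional R^2 by default, marginal with
    ``fit_mode='marginal'``); edges with weight below 0.2 are removed.
    """
    study = pd.Series(np.asarray(study), index=signatures.index)
    if condition_mask is not None:
        signatures = signatures.loc[np.asarray(condition_mask)]
        study = study.loc[signatures.index]
    if study.nunique() < 2:
        raise ValueError("coordination networks need >= 2 studies")
    # z-score each signature within study: study-constant offsets and
    # scale differences vanish, so edge weights depend only on the
    # within-study covariation the network is meant to capture
    signatures = signatures.copy()
    for st in study.unique():
        rows_st = study.index[study == st]
        block = signatures.loc[rows_st]
        sd = block.std(ddof=0)
        sd[sd == 0] = 1.0
        signatures.loc[rows_st] = (block - block.mean()) / sd
    celltypes = list(signatures.columns)
    if len(celltypes) < 4:
        raise ValueError("need >= 3 predictor cell types")
    rows, fits = [], {}
    imp = pd.DataFrame(np.nan, index=celltypes, columns=celltypes)
    for target in celltypes:
        predictors = [ct for ct in celltypes if ct != target]
        sub = signatures[[target] + predictors].dropna()
        y = sub[target].to_numpy(dtype=float)
        P = sub[predictors].to_numpy(dtype=float)
        sd = P.std(axis=0, ddof=0)
        keep = sd > 0
        dropped = [p for p, k in zip(predictors, keep) if not k]
        if dropped:
            logger.warning("target %s: constant predictors dropped: %s",
                           target, dropped)
        predictors = [p for p, k in zip(predictors, keep) if k]
        P = P[:, keep]
        X = np.column_stack([np.ones(len(y)), P])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            # drop collinear predictors greedily
            keep_cols = [0]
            names = []
            for j, name in enumerate(predictors, start=1):
                cand = X[:, keep_cols + [j]]
                if np.linalg.matrix_rank(cand) == cand.shape[1]:
                    keep_cols.append(j)
                    names.append(name)
                else:
                    logger.warning("target %s: rank-deficient predictor %s "
                                   "dropped", target, name)
            X = X[:, keep_cols]
            predictors = names
        res = fit_random_intercept(y, X, study.loc[sub.index].to_numpy())
        fit = (res.r2_conditional if fit_mode == "conditional"
               else res.r2_marginal)
        fits[target] = fit
        for j, sender in enumerate(predictors, start=1):
            coef = res.beta[j]
            weight = coef * fit
            imp.loc[sender, target] = weight
            value = abs(weight) if absolute else weight
            if value >= weight_threshold:
                rows.append({"sender": sender, "target": target,
                             "coefficient": coef, "fit": fit,
                             "weight": weight})
    edges = pd.DataFrame(rows, columns=["sender", "target", "coefficient",
                                        "fit", "weight"])
    return CoordinationNetwork(edges=edges, condition=condition, fits=fits,
                               importances=imp)


def compare_networks(net_a: CoordinationNetwork, net_b: CoordinationNetwork):
    """Compare two condition-specific networks.

    Spearman correlation over the union of unfiltered edge importances,
    plus a per-cell-type one-sample t-test of the paired differences of
    that type's outgoing importances (BH-adjusted).
    Returns ``(spearman_rho, spearman_p, shift_table)``.
    """
    ia, ib = net_a.importances, net_b.importances
    if ia is None or ib is None or list(ia.index) != list(ib.index):
        raise ValueError("networks must share the same node set")
    mask = ia.notna() & ib.notna()
    a = ia.to_numpy()[mask.to_numpy()]
    b = ib.to_numpy()[mask.to_numpy()]
    if len(a) < 3:
        raise ValueError("fewer than 3 shared edges")
    rho, p = stats.spearmanr(a, b)
    rows = []
    for ct in ia.index:
        d = (ia.loc[ct] - ib.loc[ct]).dropna().to_numpy()
        if len(d) < 2:
            continue
        if np.allclose(d, d[0]) and np.allclose(d[0], 0.0):
            t, tp = 0.0, 1.0
        else:
            t, tp = stats.ttest_1samp(d, 0.0)
        rows.append({"celltype": ct, "mean_diff": float(np.mean(d)),
                     "t": float(t), "p": float(tp)})
    shifts = pd.DataFrame(rows).set_index("celltype")
    shifts["adj_p"] = bh_adjust(shifts["p"])
    return float(rho), float(p), shifts


def lr_scores(model, factor: str, lr_table: pd.DataFrame,
              min_abs: float = WEIGHT_FLOOR) -> pd.DataFrame:
    """Ligand-receptor interaction scores across cell-type pairs.

    For each sender/receiver pair and each (ligand, receptor) row: both
    genes must carry |loading| > 0.1 in the factor in their respective
    views; the interaction score is the sum of the two loadings.
    """
    rows = []
    for sender, Ws in model.loadings.items():
        ws = Ws[factor]
        for receiver, Wr in model.loadings.items():
            if receiver == sender:
                continue
            wr = Wr[factor]
            for _, row in lr_table.iterrows():
                lig, rec = row["ligand"], row["receptor"]
                if lig not in ws.index or rec not in wr.index:
                    continue
                wl, wrv = float(ws[lig]), float(wr[rec])
                if abs(wl) > min_abs and abs(wrv) > min_abs:
                    rows.append({"sender": sender, "receiver": receiver,
                                 "ligand": lig, "receptor": rec,
                                 "ligand_loading": wl,
                                 "receptor_loading": wrv,
                                 "score": wl + wrv})
    return pd.DataFrame(rows, columns=["sender", "receiver", "ligand",
                                       "receptor", "ligand_loading",
                                       "receptor_loading", "score"])


def prioritize_ligands(sender_loadings: pd.Series, receiver_loadings: pd.Series,
                       prior_matrix: pd.DataFrame, top_frac: float = 0.10,
                       bg_frac: float = 0.30,
                       min_abs: float = WEIGHT_FLOOR) -> pd.DataFrame:
    """Corrected-AUPR ligand activity on a receiver cell type.

    Targets: the top 10% most extreme receiver loadings; background: the
    30% of receiver genes with loadings closest to zero.  For each
    expressed sender ligand (|loading| > 0.1) present in the prior, genes
    in target-union-background are ranked by prior potential and the
    AUPR of the target set, minus its prevalence (the random baseline),
    is the ligand's corrected activity.
    """
    recv = receiver_loadings.dropna()
    G = len(recv)
    n_top = int(np.ceil(top_frac * G))
    n_bg = int(np.ceil(bg_frac * G))
    by_extreme = recv.abs().sort_values(ascending=False)
    targets = list(by_extreme.index[:n_top])
    background = list(by_extreme.index[::-1][:n_bg])
    background = [g for g in background if g not in targets]
    if not targets:
        raise ValueError("empty target set")
    pool = targets + background
    rows = []
    for lig in prior_matrix.index:
        w = sender_loadings.get(lig, 0.0)
        if abs(w) <= min_abs:
            continue
        pot = prior_matrix.loc[lig].reindex(pool)
        ok = pot.notna()
        y_true = np.array([g in set(targets) for g in pot.index[ok]])
        if y_true.sum() == 0 or (~y_true).sum() == 0:
            continue
        prevalence = y_true.mean()
        aupr = average_precision(y_true, pot[ok].to_numpy())
        rows.append({"ligand": lig, "sender_loading": float(w),
                     "aupr": aupr, "prevalence": prevalence,
                     "corrected_aupr": aupr - prevalence})
    out = pd.DataFrame(rows, columns=["ligand", "sender_loading", "aupr",
                                      "prevalence", "corrected_aupr"])
    return out.sort_values("corrected_aupr", ascending=False).reset_index(drop=True)
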