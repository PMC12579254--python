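"""Shared enrichment statistics.

* ``ulm_score``: univariate-linear-model signature scoring — the t-value
  of the slope from regressing a sample's expression on a gene-weight
  vector (weights with |w| < 0.1 excluded by default).
* ``hypergeom_ora``: upper-tail hypergeometric over-representation with
  BH correction per gene-set collection.
* ``extract_programs``: directed (positive/negative) gene programs from
  factor loadings, with the multicellular vs cell-type-specific split.
* ``functional_vectors``: 2-D enrichment vectors for two factors, each
  component = overlap fraction x (1 - p), signed by direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust

__all__ = [
    "DirectedProgram",
    "ulm_score",
    "ulm_score_matrix",
    "hypergeom_ora",
    "ora_table",
    "extract_programs",
    "functional_vectors",
    "read_gmt",
    "write_gmt",
]

WEIGHT_FLOOR = 0.1  # |loading| below this is excluded from signatures


@dataclass
class DirectedProgram:
    """Directed gene sets of one (factor, cell type) pair."""

    factor: str
    celltype: str
    positive: set
    negative: set
    multicellular: set = field(default_factory=set)  # genes in > 1 cell type
    specific: set = field(default_factory=set)

    @property
    def genes(self) -> set:
        return self.positive | self.negative


def ulm_score(profile, weights, min_abs: float = WEIGHT_FLOOR,
              min_genes: int = 3) -> float:
    """t-statistic of the slope regressing expression on gene weights.

    ``profile`` and ``weights`` are aligned pandas Series (or arrays);
    weights with |w| < ``min_abs`` are dropped before the fit.
    """
    if isinstance(profile, pd.Series) and isinstance(weights, pd.Series):
        shared = weights.index.intersection(profile.index)
        w = weights.loc[shared].to_numpy(dtype=float)
        y = profile.loc[shared].to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        y = np.asarray(profile, dtype=float)
    keep = np.abs(w) >= min_abs
    w, y = w[keep], y[keep]
    if len(w) < min_genes:
        raise ValueError(f"fewer than {min_genes} genes after the weight filter")
    if np.ptp(w) == 0:
        raise ValueError("constant weights")
    n = len(w)
    wc = w - w.mean()
    yc = y - y.mean()
    sxx = float(wc @ wc)
    slope = float(wc @ yc) / sxx
    resid = yc - slope * wc
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    return float(slope / se) if se > 0 else np.inf * np.sign(slope)


def ulm_score_matrix(expr: pd.DataFrame, weights: pd.Series,
                     min_abs: float = WEIGHT_FLOOR,
                     min_genes: int = 3) -> pd.Series:
    """Vectorized ``ulm_score`` over all columns of an expression matrix."""
    shared = weights.index.intersection(expr.index)
    w = weights.loc[shared].to_numpy(dtype=float)
    keep = np.abs(w) >= min_abs
    if keep.sum() < min_genes:
        raise ValueError(f"fewer than {min_genes} genes after the weight filter")
    w = w[keep]
    Y = expr.loc[shared].to_numpy(dtype=float)[keep]
    n = len(w)
    wc = w - w.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sxx = float(wc @ wc)
    slope = (wc @ Yc) / sxx
    resid = Yc - np.outer(wc, slope)
    s2 = (resid ** 2).sum(axis=0) / (n - 2)
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.divide(slope, se, out=np.full_like(slope, np.inf), where=se > 0)
    return pd.Series(t, index=expr.columns, name="ulm_t")


def hypergeom_ora(program_set, functional_set, universe):
    """Upper-tail hypergeometric over-representation test.

    Returns ``(p, overlap, fold)`` where fold is the observed/expected
    overlap ratio.  ``p = P(X >= overlap)`` (so zero overlap gives 1).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(program_set) & universe
    B = set(functional_set) & universe
    N, K, n = len(universe), len(B), len(A)
    k = len(A & B)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    expected = K * n / N
    fold = k / expected if expected > 0 else np.nan
    return p, k, fold


def ora_table(programs: dict, collection: dict, universe) -> pd.DataFrame:
    """ORA of each program against each set of one collection.

    BH correction is applied within the collection, independently per
    program (corrections per functional gene-set collection).
    """
    rows = []
    for pname, pgenes in programs.items():
        for sname, sgenes in collection.items():
            p, k, fold = hypergeom_ora(pgenes, sgenes, universe)
            denom = len(set(pgenes) & set(universe))
            rows.append({"program": pname, "set": sname, "p": p, "overlap": k,
                         "fold": fold,
                         "overlap_frac": k / denom if denom else 0.0})
    out = pd.DataFrame(rows)
    out["adj_p"] = np.nan
    for pname in programs:
        m = out["program"] == pname
        out.loc[m, "adj_p"] = bh_adjust(out.loc[m, "p"])
    return out


def extract_programs(model, factor: str, weight_floor: float = 0.0) -> dict:
    """Directed gene programs of one factor across cell-type views.

    Genes with |loading| > ``weight_floor`` enter the program, split into
    positive and negative directions; genes relevant in more than one
    cell type form the multicellular component, the rest are
    cell-type-specific.
    """
    per_view = {}
    gene_views: dict = {}
    for ct, W in model.loadings.items():
        w = W[factor]
        pos = set(w.index[w > weight_floor])
        neg = set(w.index[w < -weight_floor])
        per_view[ct] = DirectedProgram(factor=factor, celltype=ct,
                                       positive=pos, negative=neg)
        for g in pos | neg:
            gene_views.setdefault(g, set()).add(ct)
    multicellular = {g for g, cts in gene_views.items() if len(cts) > 1}
    for prog in per_view.values():
        prog.multicellular = prog.genes & multicellular
        prog.specific = prog.genes - multicellular
    return per_view


def functional_vectors(ora_by_component: dict, adj_p_cut: float = 0.1,
                       use_adjusted_magnitude: bool = False) -> pd.DataFrame:
    """2-D functional vectors from four directed-program ORA tables.

    ``ora_by_component`` maps the component keys ``(axis, direction)``
    with axis in {0, 1} (factor 1 = x, factor 2 = y) and direction in
    {+1, -1} to ORA tables from :func:`ora_table` (single program each).
    A set enters if its BH-adjusted p is <= ``adj_p_cut`` in at least one
    component; each component contributes
    ``direction * overlap_frac * (1 - p)`` (raw p by default, the
    adjusted p gates inclusion only).
    """
    sets: set = set()
    for tab in ora_by_component.values():
        sets |= set(tab["set"])
    rows = []
    pcol = "adj_p" if use_adjusted_magnitude else "p"
    for s in sorted(sets):
        vec = np.zeros(2)
        min_adj = np.inf
        for (axis, direction), tab in ora_by_component.items():
            row = tab[tab["set"] == s]
            if row.empty:
                continue
            row = row.iloc[0]
            min_adj = min(min_adj, row["adj_p"])
            vec[axis] += direction * row["overlap_frac"] * (1.0 - row[pcol])
        if min_adj <= adj_p_cut:
            rows.append({"set": s, "x": vec[0], "y": vec[1]})
    return pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["x", "y"])


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def write_gmt(sets: dict, path, description: str = "mcpmap") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + sorted(genes)) + "\n")
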