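"""Cohort I/O, cell-type label harmonization and pseudobulk QC.

Cell annotations from different studies are mapped onto a fixed 7-type
cardiac ontology (CM, Fib, Endo, PC, vSMC, Myeloid, Lymphoid) by ordered
regular-expression rules; unmatched labels are discarded.  Cell-level
matrices are pseudobulked by summing counts per (sample, cell type), and
each pseudobulk profile gets a contamination score: the ratio of reads on
other cell types' marker genes to reads on its own type's markers.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VALID_CELL_TYPES",
    "DISCARD",
    "OntologyMap",
    "CohortViews",
    "harmonize_labels",
    "pseudobulk",
    "contamination_score",
    "read_views_tsv",
    "write_views_tsv",
]

logger = logging.getLogger(__name__)

VALID_CELL_TYPES = frozenset({"CM", "Fib", "Endo", "PC", "vSMC", "Myeloid", "Lymphoid"})
DISCARD = "discard"

METADATA_VOCAB = {
    "disease": {"HF", "NF"},
    "etiology": {"DCM", "ICM", "HCM", "ARVC", "other", "NF"},
}


@dataclass
class OntologyMap:
    """Ordered (regex, target) rules mapping raw labels to the ontology.

    The first matching pattern wins; labels matching no pattern map to
    ``discard``.
    """

    patterns: list  # list of (pattern_str, target_label)

    def __post_init__(self):
        compiled = []
        for pat, target in self.patterns:
            if target not in VALID_CELL_TYPES and target != DISCARD:
                raise ValueError(f"target {target!r} not in the 7-type ontology")
            try:
                compiled.append((re.compile(pat), target))
            except re.error as exc:
                raise ValueError(f"malformed pattern {pat!r}: {exc}") from exc
        self._compiled = compiled

    @classmethod
    def from_yaml(cls, path) -> "OntologyMap":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(patterns=[(d["pattern"], d["target"]) for d in raw])

    def map_label(self, label: str) -> str:
        hits = [t for rx, t in self._compiled if rx.search(str(label))]
        if not hits:
            return DISCARD
        if len(set(hits)) > 1:
            logger.warning("label %r matches multiple targets %s; first wins",
                           label, hits)
        return hits[0]


@dataclass
class CohortViews:
    """Per (study, cell type) pseudobulk count matrices with metadata.

    Absent (sample, type) combinations are represented by missing columns,
    never zero-filled; downstream filters act on presence.
    """

    views: dict                    # (study, celltype) -> genes x samples
    metadata: pd.DataFrame         # indexed by sample id
    qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        for key, mat in self.views.items():
            missing = [c for c in mat.columns if c not in self.metadata.index]
            if missing:
                raise ValueError(f"view {key}: samples without metadata: {missing[:5]}")
            if (mat.to_numpy() < 0).any():
                raise ValueError(f"view {key}: negative counts")

    def studies(self) -> list:
        return sorted({s for s, _ in self.views})

    def celltypes(self) -> list:
        return sorted({ct for _, ct in self.views})

    @classmethod
    def from_cohort(cls, cohort) -> "CohortViews":
        return cls(views={k: v.copy() for k, v in cohort.views.items()},
                   metadata=cohort.metadata.copy(), qc=cohort.qc.copy())


def harmonize_labels(raw_labels, omap: OntologyMap):
    """Map raw annotations to the ontology; returns (labels, discard_mask, report)."""
    if not omap.patterns:
        raise ValueError("ontology map is empty")
    mapped = [omap.map_label(lab) for lab in raw_labels]
    mask = np.array([m == DISCARD for m in mapped])
    report = pd.Series(mapped).value_counts().to_dict()
    if mask.any():
        logger.info("discarded %d/%d cells with unmatched labels",
                    int(mask.sum()), len(mapped))
    return mapped, mask, report


def pseudobulk(cell_counts: pd.DataFrame, cell_labels, sample_ids,
               metadata: pd.DataFrame | None = None) -> CohortViews:
    """Sum cell-level counts into per (sample, cell type) pseudobulks.

    ``cell_counts`` is genes x cells. Cells labelled ``discard`` are
    dropped. (sample, type) combinations with zero cells yield no column.
    """
    n_cells = cell_counts.shape[1]
    if len(cell_labels) != n_cells or len(sample_ids) != n_cells:
        raise ValueError("cell_labels and sample_ids must match the cell count")
    labels = np.asarray(cell_labels)
    samples = np.asarray(sample_ids)
    keep = labels != DISCARD
    X = cell_counts.to_numpy()[:, keep]
    labels, samples = labels[keep], samples[keep]

    views: dict = {}
    qc_rows = []
    study = "study0" if metadata is None else None
    for ct in np.unique(labels):
        cols = {}
        for sid in np.unique(samples):
            sel = (labels == ct) & (samples == sid)
            if not sel.any():
                continue
            cols[sid] = X[:, sel].sum(axis=1)
            qc_rows.append({
                "sample": sid, "celltype": ct, "n_cells": int(sel.sum()),
                "total_reads": int(cols[sid].sum()),
                "genes_detected": int((cols[sid] > 0).sum()),
            })
        if cols:
            mat = pd.DataFrame(cols, index=cell_counts.index)
            st = study if study is not None else metadata.loc[mat.columns[0], "study"]
            views[(st, ct)] = mat
    if metadata is None:
        metadata = pd.DataFrame(
            {"study": "study0", "disease": pd.NA},
            index=pd.Index(np.unique(samples), name="sample"))
    return CohortViews(views=views, metadata=metadata, qc=pd.DataFrame(qc_rows))


def contamination_score(view: pd.DataFrame, markers_by_type: dict,
                        own_type: str) -> pd.Series:
    """Ambient-contamination score per pseudobulk profile.

    score = reads on other types' markers / reads on own-type markers.
    A gene marking both the tested type and another type counts toward the
    own-marker denominator only.  Zero own-marker reads give +inf with a
    warning.  The score is a ratio of read shares, hence invariant to
    library-size scaling.
    """
    if own_type not in markers_by_type:
        raise KeyError(f"no marker set for {own_type!r}")
    own = set(markers_by_type[own_type])
    contaminating = set()
    for ct, genes in markers_by_type.items():
        if ct != own_type:
            contaminating |= set(genes)
    contaminating -= own  # shared markers credit the tested type
    own_genes = [g for g in view.index if g in own]
    cont_genes = [g for g in view.index if g in contaminating]
    own_reads = view.loc[own_genes].sum(axis=0).astype(float)
    cont_reads = view.loc[cont_genes].sum(axis=0).astype(float)
    if (own_reads == 0).any():
        warnings.warn("profiles with zero own-marker reads: contamination "
                      "score set to +inf", RuntimeWarning, stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = cont_reads / own_reads
    score[own_reads == 0] = np.inf
    score.name = "contamination_score"
    return score


def write_views_tsv(views: CohortViews, outdir) -> None:
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (study, ct), mat in views.views.items():
        mat.to_csv(out / f"counts_{study}_{ct}.tsv", sep="\t")
    views.metadata.to_csv(out / "metadata.tsv", sep="\t")
    if len(views.qc):
        views.qc.to_csv(out / "qc.tsv", sep="\t", index=False)


def read_views_tsv(indir) -> CohortViews:
    from pathlib import Path

    ind = Path(indir)
    metadata = pd.read_csv(ind / "metadata.tsv", sep="\t", index_col=0)
    qc_path = ind / "qc.tsv"
    qc = pd.read_csv(qc_path, sep="\t") if qc_path.exists() else pd.DataFrame()
    views = {}
    for f in sorted(ind.glob("counts_*_*.tsv")):
        study, ct = f.stem[len("counts_"):].rsplit("_", 1)
        views[(study, ct)] = pd.read_csv(f, sep="\t", index_col=0)
    return CohortViews(views=views, metadata=metadata, qc=qc)
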