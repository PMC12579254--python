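"""Synthetic multi-study heart-tissue cohort generator with known ground truth.

The generator emulates the statistical structure of a cross-study
single-nucleus + bulk heart-failure compendium:

* several studies, each with failing (HF) and non-failing (NF) arms and
  study-level batch effects on the log scale;
* seven cardiac cell types (CM, Fib, Endo, PC, vSMC, Myeloid, Lymphoid)
  with disjoint planted marker genes;
* a planted *multicellular program*: a latent per-sample factor, shifted
  under disease, whose gene loadings span several cell-type views so that
  expression changes are coordinated across cell types;
* Dirichlet cell-type compositions with disease-dependent shifts
  (cardiomyocytes and pericytes shrink, immune cells expand by default);
* overdispersed counts (Gamma-Poisson) with ambient contamination mixed
  in as a convex combination with the cell-count-weighted pooled profile;
* bulk mixtures as composition-weighted expected cell-type profiles;
* fibroblast sub-state pseudobulks carrying specialist / generalist /
  acquired-generalist gene classes;
* a pluggable ligand-receptor prior with planted true ligands.

Every planted quantity is recorded in :class:`CohortTruth` so that each
downstream stage can be benchmarked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "SimConfig",
    "SimConfigError",
    "CohortTruth",
    "SyntheticCohort",
    "FibroStateSim",
    "LigandPrior",
    "simulate_cohort",
    "simulate_cells",
    "simulate_bulk",
    "simulate_fibro_states",
    "simulate_ligand_prior",
]

CELL_TYPES = ("CM", "Fib", "Endo", "PC", "vSMC", "Myeloid", "Lymphoid")

# default Dirichlet concentrations: CM-dominated tissue
_DEFAULT_DIRICHLET = (14.0, 10.0, 9.0, 4.0, 3.0, 5.0, 4.0)
# default disease log-shifts of concentrations: every type but the
# fibroblasts changes, CM and PC decrease, lymphoid cells increase most
_DEFAULT_COMP_SHIFT = (-0.5, 0.0, 0.2, -0.4, -0.2, 0.3, 0.6)


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    ``mcp_effect`` is the disease shift of the planted program factor in
    within-study standard-deviation units; ``batch_sd`` the SD of study
    offsets on the natural-log scale; ``nb_dispersion`` the Gamma-Poisson
    dispersion (variance = m + dispersion * m^2); ``ambient_rho`` the
    contamination mixing fraction.
    """

    n_studies: int = 4
    samples_per_arm: int = 30
    n_celltypes: int = 7
    n_genes: int = 1200
    n_markers_per_type: int = 25
    mcp_effect: float = 1.5
    batch_sd: float = 0.5
    nb_dispersion: float = 0.3
    ambient_rho: float = 0.05
    dirichlet_base: tuple = _DEFAULT_DIRICHLET
    comp_shift: tuple = _DEFAULT_COMP_SHIFT
    libsize_range: tuple = (0.7, 1.3)
    cells_per_sample: int = 1500
    marker_log2fc: float = 3.0
    program_pool_size: int = 120
    program_genes_per_type: int = 40
    marker_program_frac: float = 0.3
    baseline_log_mean: float = np.log(60.0)
    baseline_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_studies", "samples_per_arm", "n_celltypes", "n_genes",
                     "n_markers_per_type", "cells_per_sample"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if not 0.0 <= self.ambient_rho < 1.0:
            raise SimConfigError("ambient_rho must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise SimConfigError("nb_dispersion must be >= 0")
        if len(self.dirichlet_base) != self.n_celltypes:
            raise SimConfigError("dirichlet_base length must match n_celltypes")
        if np.any(np.asarray(self.dirichlet_base) <= 0):
            raise SimConfigError("dirichlet_base must be strictly positive")
        if len(self.comp_shift) != self.n_celltypes:
            raise SimConfigError("comp_shift length must match n_celltypes")
        if not (0 < self.libsize_range[0] <= self.libsize_range[1]):
            raise SimConfigError("libsize_range must be positive and ordered")
        if self.n_celltypes * self.n_markers_per_type > self.n_genes:
            raise SimConfigError("marker genes exceed the gene universe")
        if not 0.0 <= self.marker_program_frac <= 1.0:
            raise SimConfigError("marker_program_frac must be in [0, 1]")

    @property
    def celltypes(self) -> tuple:
        return CELL_TYPES[: self.n_celltypes]


@dataclass
class CohortTruth:
    """Ground truth planted by the generator."""

    loadings: pd.DataFrame          # genes x cell types, program loadings w
    factor_scores: pd.Series        # per-sample latent factor f
    compositions: pd.DataFrame      # samples x cell types, realized props
    marker_sets: dict               # cell type -> set of marker genes
    comp_shift: dict                # cell type -> disease concentration shift
    nppa_like: list                 # shrinking-type markers with +ve loadings
    expected_profiles: dict = field(default_factory=dict)
    # (study, celltype) -> genes x samples expected (noise-free) rates


@dataclass
class SyntheticCohort:
    views: dict                     # (study, celltype) -> genes x samples counts
    metadata: pd.DataFrame          # sample table (study, disease, sex, ...)
    qc: pd.DataFrame                # per (sample, celltype) QC metrics
    truth: CohortTruth
    config: SimConfig

    def studies(self) -> list:
        return sorted({s for s, _ in self.views})

    def write(self, outdir) -> None:
        """Write views/metadata as TSV, truth as JSON, markers as GMT."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for (study, ct), mat in self.views.items():
            mat.to_csv(out / f"counts_{study}_{ct}.tsv", sep="\t")
        self.metadata.to_csv(out / "metadata.tsv", sep="\t")
        self.qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        self.truth.compositions.to_csv(out / "true_compositions.tsv", sep="\t")
        truth = {
            "factor_scores": self.truth.factor_scores.to_dict(),
            "comp_shift": self.truth.comp_shift,
            "nppa_like": list(self.truth.nppa_like),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        with open(out / "true_markers.gmt", "w") as fh:
            for ct, genes in self.truth.marker_sets.items():
                fh.write("\t".join([f"{ct}_markers", "planted"] + sorted(genes)) + "\n")


def _gene_names(n: int) -> list:
    return [f"g{i:04d}" for i in range(n)]


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson counts: variance = m + dispersion * m^2."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the multi-study, multi-cell-type pseudobulk cohort.

    Log-rate of gene g in cell type k for sample i:
    ``baseline_g + marker block + f_i * w_{g,k} + batch(study_i, k, g)``;
    counts are Gamma-Poisson draws scaled by a per-profile library factor
    and then convex-mixed with the pooled ambient profile at fraction
    ``ambient_rho``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    celltypes = config.celltypes
    genes = _gene_names(G)

    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, G)

    # disjoint marker blocks, one per cell type
    marker_sets: dict = {}
    marker_matrix = np.zeros((G, len(celltypes)))
    cursor = 0
    for k, ct in enumerate(celltypes):
        block = list(range(cursor, cursor + config.n_markers_per_type))
        cursor += config.n_markers_per_type
        marker_sets[ct] = {genes[i] for i in block}
        marker_matrix[block, k] = config.marker_log2fc * np.log(2.0)

    # planted multicellular program: shared pool, per-view loaded subsets
    non_marker = np.arange(cursor, G)
    pool = rng.choice(non_marker, size=min(config.program_pool_size, len(non_marker)),
                      replace=False)
    W = np.zeros((G, len(celltypes)))
    for k in range(len(celltypes)):
        chosen = rng.choice(pool, size=min(config.program_genes_per_type, len(pool)),
                            replace=False)
        signs = np.where(rng.random(len(chosen)) < 0.5, 1.0, -1.0)
        W[chosen, k] = signs * rng.uniform(0.5, 1.0, len(chosen))

    # a fraction of each type's markers is also molecularly deregulated
    # (program-loaded in its own view), emulating the observed share of
    # disease-deregulated marker genes; markers of shrinking cell types
    # that are UP-regulated by the program are the NPPA-like genes
    # (molecular up-regulation despite compositional decrease)
    nppa_like: list = []
    gene_pos = {g: i for i, g in enumerate(genes)}
    shifts = np.asarray(config.comp_shift, dtype=float)
    for k, ct in enumerate(celltypes):
        m = int(round(config.marker_program_frac * config.n_markers_per_type))
        if m == 0:
            continue
        chosen = rng.choice(sorted(marker_sets[ct]), size=m, replace=False)
        signs = np.where(rng.random(m) < 0.5, 1.0, -1.0)
        if shifts[k] < 0:
            signs = np.abs(signs)  # shrinking types get up-regulated markers
        W[[gene_pos[g] for g in chosen], k] = signs * rng.uniform(0.5, 1.0, m)
        if shifts[k] < 0:
            nppa_like.extend(str(g) for g in chosen)

    # samples and metadata
    rows = []
    for s in range(config.n_studies):
        study = f"study{s}"
        for arm, disease in (("HF", "HF"), ("NF", "NF")):
            for i in range(config.samples_per_arm):
                rows.append({
                    "sample": f"{study}_{arm}{i:02d}",
                    "study": study,
                    "disease": disease,
                    "sex": rng.choice(["F", "M"]),
                    "age": float(np.round(rng.normal(58, 10), 1)),
                    "etiology": (rng.choice(["DCM", "ICM", "other"])
                                 if disease == "HF" else "NF"),
                })
    metadata = pd.DataFrame(rows).set_index("sample")
    n_samples = len(metadata)
    is_hf = (metadata["disease"] == "HF").to_numpy()

    # latent program factor, standardized within study
    f = config.mcp_effect * is_hf + rng.normal(0.0, 1.0, n_samples)
    for study in metadata["study"].unique():
        m = (metadata["study"] == study).to_numpy()
        f[m] = (f[m] - f[m].mean()) / f[m].std(ddof=0)
    factor_scores = pd.Series(f, index=metadata.index, name="f")

    # compositions and per-sample cell counts
    alpha = np.asarray(config.dirichlet_base, dtype=float)
    shift = np.exp(np.asarray(config.comp_shift, dtype=float))
    props = np.empty((n_samples, len(celltypes)))
    cells = np.empty((n_samples, len(celltypes)), dtype=int)
    for i in range(n_samples):
        a = alpha * shift if is_hf[i] else alpha
        p = rng.dirichlet(a)
        cells[i] = rng.multinomial(config.cells_per_sample, p)
        tot = cells[i].sum()
        props[i] = cells[i] / tot if tot else p
    compositions = pd.DataFrame(props, index=metadata.index, columns=celltypes)

    # batch offsets per (study, view, gene)
    studies = list(metadata["study"].unique())
    batch = {
        (study, ct): rng.normal(0.0, config.batch_sd, G)
        for study in studies for ct in celltypes
    }

    views: dict = {}
    expected: dict = {}
    qc_rows = []
    lo, hi = config.libsize_range
    for study in studies:
        smask = (metadata["study"] == study).to_numpy()
        sample_ids = metadata.index[smask]
        f_s = f[smask]
        # expected rates per view for this study's samples
        mus = {}
        for k, ct in enumerate(celltypes):
            eta = (baseline[:, None] + marker_matrix[:, [k]]
                   + np.outer(W[:, k], f_s) + batch[(study, ct)][:, None])
            mus[ct] = np.exp(eta)
        # pooled ambient profile per sample: cell-count-weighted view mix
        cell_w = cells[smask]  # samples x celltypes
        pooled = np.zeros((G, len(sample_ids)))
        for k, ct in enumerate(celltypes):
            pooled += mus[ct] * cell_w[:, k][None, :]
        pooled /= np.clip(pooled.sum(axis=0, keepdims=True), 1e-12, None)

        for k, ct in enumerate(celltypes):
            libf = rng.uniform(lo, hi, len(sample_ids))
            mean = mus[ct] * libf[None, :]
            counts = _draw_counts(rng, mean, config.nb_dispersion)
            if config.ambient_rho > 0:
                kept = rng.binomial(counts, 1.0 - config.ambient_rho)
                total = mean.sum(axis=0)
                ambient = rng.poisson(config.ambient_rho * total[None, :] * pooled)
                counts = kept + ambient
            keep_cols = cell_w[:, k] > 0
            mat = pd.DataFrame(counts[:, keep_cols], index=genes,
                               columns=sample_ids[keep_cols])
            views[(study, ct)] = mat
            expected[(study, ct)] = pd.DataFrame(
                mus[ct][:, keep_cols], index=genes, columns=sample_ids[keep_cols])
            for j, sid in enumerate(sample_ids):
                if not keep_cols[j]:
                    continue
                col = counts[:, j]
                qc_rows.append({
                    "sample": sid, "celltype": ct,
                    "n_cells": int(cell_w[j, k]),
                    "total_reads": int(col.sum()),
                    "genes_detected": int((col > 0).sum()),
                })

    truth = CohortTruth(
        loadings=pd.DataFrame(W, index=genes, columns=celltypes),
        factor_scores=factor_scores,
        compositions=compositions,
        marker_sets=marker_sets,
        comp_shift=dict(zip(celltypes, config.comp_shift)),
        nppa_like=nppa_like,
        expected_profiles=expected,
    )
    return SyntheticCohort(views=views, metadata=metadata,
                           qc=pd.DataFrame(qc_rows), truth=truth, config=config)


def simulate_cells(config: SimConfig, n_cells: int = 300, seed: int | None = None):
    """Small cell-level count matrix with labels and sample ids.

    Intended for exercising pseudobulking: cells are Poisson draws around
    a per-type mean profile at 1/50 pseudobulk depth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    G = config.n_genes
    genes = _gene_names(G)
    celltypes = config.celltypes
    baseline = rng.normal(config.baseline_log_mean - np.log(50.0), 0.8, G)
    labels = rng.choice(celltypes, size=n_cells)
    samples = rng.choice([f"s{i}" for i in range(4)], size=n_cells)
    counts = np.empty((G, n_cells), dtype=int)
    type_shift = {ct: rng.normal(0, 0.3, G) for ct in celltypes}
    for j in range(n_cells):
        counts[:, j] = rng.poisson(np.exp(baseline + type_shift[labels[j]]))
    mat = pd.DataFrame(counts, index=genes,
                       columns=[f"cell{j:04d}" for j in range(n_cells)])
    return mat, list(labels), list(samples)


def simulate_bulk(cohort: SyntheticCohort, noise_sd: float = 0.1,
                  seed: int | None = None):
    """Bulk mixtures: composition-weighted expected cell-type profiles.

    Each cell type's expected (noise-free) profile is scaled to a common
    library (1e6) and mixed by the sample's true composition; multiplicative
    log-normal noise with SD ``noise_sd`` is applied per gene.

    Returns ``(bulk, true_props)`` with ``bulk`` genes x samples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    genes = _gene_names(cohort.config.n_genes)
    celltypes = cohort.config.celltypes
    props = cohort.truth.compositions
    cols = {}
    for sid in cohort.metadata.index:
        study = cohort.metadata.loc[sid, "study"]
        mix = np.zeros(len(genes))
        for ct in celltypes:
            prof = cohort.truth.expected_profiles.get((study, ct))
            if prof is None or sid not in prof.columns:
                continue
            v = prof[sid].to_numpy()
            v = v / v.sum() * 1e6
            mix += props.loc[sid, ct] * v
        if noise_sd > 0:
            mix = mix * np.exp(rng.normal(0.0, noise_sd, len(genes)))
        cols[sid] = mix
    bulk = pd.DataFrame(cols, index=genes)
    return bulk, props.copy()


@dataclass
class FibroStateSim:
    """Fibroblast sub-state pseudobulks with planted labor classes."""

    expr: pd.DataFrame          # genes x (patient, state) log-expression
    meta: pd.DataFrame          # per column: patient, study, disease, state
    labor_truth: pd.Series      # gene -> specialist/generalist/acquired_generalist/none
    state_markers: dict         # state -> genes ranked by planted state effect
    state_comp_change: pd.Series  # planted per-state compositional disease shift


def simulate_fibro_states(config: SimConfig, n_states: int = 6,
                          n_genes_per_class: int = 15,
                          state_effect: float = 0.8, hf_effect: float = 0.8,
                          noise_sd: float = 0.3,
                          seed: int | None = None) -> FibroStateSim:
    """Patient x state pseudobulks carrying division-of-labor gene classes.

    * specialist: state-specific mean, no disease term;
    * generalist: disease shift identical across states;
    * acquired generalist: both;
    * none: neither.

    Effect sizes default to 0.8 log-units against residual SD 0.3, so the
    planted semi-partial R-squared values clear (or stay below) the 0.1
    classification threshold with margin.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    config.validate()
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    classes = ["specialist", "generalist", "acquired_generalist", "none"]
    G = n_genes_per_class * len(classes)
    genes = [f"fg{i:03d}" for i in range(G)]
    labor = pd.Series(np.repeat(classes, n_genes_per_class), index=genes)

    states = [f"state{s}" for s in range(n_states)]
    cols, meta_rows = [], []
    for s in range(config.n_studies):
        study = f"study{s}"
        for arm in ("HF", "NF"):
            for i in range(config.samples_per_arm):
                patient = f"{study}_{arm}{i:02d}"
                for st in states:
                    cols.append(f"{patient}__{st}")
                    meta_rows.append({"column": f"{patient}__{st}",
                                      "patient": patient, "study": study,
                                      "disease": arm, "state": st})
    meta = pd.DataFrame(meta_rows).set_index("column")

    base = rng.normal(5.0, 1.0, G)
    state_off = rng.normal(0.0, state_effect, (G, n_states))
    hf_delta = rng.choice([-hf_effect, hf_effect], size=G)
    uses_state = labor.isin(["specialist", "acquired_generalist"]).to_numpy()
    uses_hf = labor.isin(["generalist", "acquired_generalist"]).to_numpy()
    state_off[~uses_state] = 0.0
    hf_delta[~uses_hf] = 0.0

    study_off = {f"study{s}": rng.normal(0, 0.2, G)
                 for s in range(config.n_studies)}
    patient_off = {p: rng.normal(0, 0.15, G) for p in meta["patient"].unique()}

    expr = np.empty((G, len(cols)))
    st_index = {st: j for j, st in enumerate(states)}
    for c, col in enumerate(cols):
        m = meta.loc[col]
        expr[:, c] = (base
                      + state_off[:, st_index[m["state"]]]
                      + hf_delta * (m["disease"] == "HF")
                      + study_off[m["study"]] + patient_off[m["patient"]]
                      + rng.normal(0, noise_sd, G))
    expr = pd.DataFrame(expr, index=genes, columns=cols)

    # truth-derived per-state marker rankings (by planted state effect)
    markers = {}
    for st, j in st_index.items():
        contrast = state_off[:, j] - state_off.mean(axis=1)
        markers[st] = [genes[i] for i in np.argsort(-contrast)]
    # planted compositional change per state (expanding states first)
    change = np.linspace(1.0, -1.0, n_states)
    state_comp_change = pd.Series(change, index=states)
    return FibroStateSim(expr=expr, meta=meta, labor_truth=labor,
                         state_markers=markers,
                         state_comp_change=state_comp_change)


@dataclass
class LigandPrior:
    lr_table: pd.DataFrame      # columns: ligand, receptor
    potential: pd.DataFrame     # ligands x genes prior potential, >= 0
    true_ligands: list
    target_sets: dict           # ligand -> planted target genes


def simulate_ligand_prior(config: SimConfig, n_ligands: int = 12,
                          n_true: int = 4, target_size: int = 60,
                          loadings: pd.Series | None = None,
                          seed: int | None = None) -> LigandPrior:
    """Ligand-receptor table plus ligand-to-target prior potentials.

    True ligands' potential rows concentrate on their planted target set
    (by default the genes with the most extreme values of ``loadings``,
    i.e. the receiver view's program genes); decoy ligands get uniform
    random potentials.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 13 if seed is None else seed)
    genes = _gene_names(config.n_genes)
    ligands = [f"L{i:02d}" for i in range(n_ligands)]
    receptors = [f"R{i:02d}" for i in range(n_ligands)]
    lr_table = pd.DataFrame({"ligand": ligands, "receptor": receptors})

    if loadings is not None:
        ranked = loadings.abs().sort_values(ascending=False).index.tolist()
        target_pool = ranked[:target_size]
    else:
        target_pool = list(rng.choice(genes, size=target_size, replace=False))

    potential = rng.uniform(0.0, 1.0, (n_ligands, len(genes)))
    true_ligands = ligands[:n_true]
    target_sets = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for li, lig in enumerate(true_ligands):
        targets = target_pool
        row = rng.uniform(0.0, 0.05, len(genes))
        row[[gene_pos[g] for g in targets]] = rng.uniform(0.7, 1.0, len(targets))
        potential[li] = row
        target_sets[lig] = list(targets)
    potential = pd.DataFrame(potential, index=ligands, columns=genes)
    return LigandPrior(lr_table=lr_table, potential=potential,
                       true_ligands=true_ligands, target_sets=target_sets)
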