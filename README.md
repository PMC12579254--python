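# mcpmap

Cross-study multicellular program analysis of heart-failure
transcriptomics.

Heart failure (HF) reshapes cardiac tissue on two coupled axes: the
*composition* of the tissue changes (cardiomyocytes and pericytes become
less abundant, immune cells expand) and the *expression state* of each
cell type changes. Single-nucleus studies resolve both axes but are
small and batch-ridden; bulk studies are plentiful but mix the axes
together. `mcpmap` implements an integration toolkit for this setting,
built around the idea of a **multicellular program (MCP)**: a latent
per-sample factor whose gene loadings span several cell-type *views*
(gene × sample pseudobulk matrices), capturing coordinated expression
changes across cell types.

The toolkit covers, end to end:

- **Cohort harmonization** — regex-based mapping of cell annotations to a
  7-type cardiac ontology (CM, Fib, Endo, PC, vSMC, Myeloid, Lymphoid),
  pseudobulking, and a marker-ratio contamination score.
- **Normalization & differential expression** — TMM factors, log-CPM, a
  moderated-t contrast (posterior variance
  `(d0*s0² + d*s²)/(d0 + d)`), one-vs-rest cell-type markers
  (log2FC > 2, FDR < 0.01), Fisher combined meta-analysis
  (`-2 Σ ln p ~ χ²(2k)`), and Jaccard marker agreement.
- **Transferable disease scores** — a test sample's score is
  `Σ_g z_g · t_g` over a reference study's top-500 differential genes;
  transfer is measured by AUROC. An analogous score works on
  centered-log-ratio (clr) cell-type compositions.
- **The MCP factor model** — after a filter cascade (≥20 cells per
  pseudobulk, view coverage ≥40% of samples, expression filters,
  cross-cell-type marker removal, ≥97% gene coverage per sample), a
  K-factor model minimizing `Σ_v ||M_v ⊙ (X_v − W_v Zᵀ)||² / p_v` is fit
  by masked alternating least squares with per-study centering —
  deterministic, initialized from an SVD.
- **Projection & classification** — external cohorts map into factor
  space through the Moore–Penrose pseudoinverse of the concatenated
  loadings; LDA and logistic classifiers transfer the HF/NF boundary;
  cohorts without controls standardize against a healthy reference.
- **Coordination networks** — mixed models predict each cell type's
  program signature from the others' (study as random intercept); edge
  weight = coefficient × model fit, threshold 0.2.
- **Ligand–receptor analysis** — interaction score = sum of ligand and
  receptor loadings (|w| > 0.1); ligand activity ranked by corrected
  AUPR of a ligand→target prior against the receiver's extreme loadings.
- **Deregulation annotation & deconvolution** — each consensus bulk gene
  is classed compositional / molecular / both / unknown by sign
  agreement; NNLS deconvolution with marker-subset signature matrices
  quantifies how molecularly deregulated markers degrade composition
  estimates.
- **Division of labor** — semi-partial R² from
  `ES ~ HF + state + (1|study) + (1|patient)` classifies genes as
  specialist / generalist / acquired generalist at the 0.1 threshold.

Everything is exercised on a synthetic multi-study cohort generator
(`mcpmap.cohort_synth`) with planted ground truth for every stage, so no
external data are needed.

## Worked example

```python
import numpy as np
from mcpmap.cohort_synth import SimConfig, simulate_cohort, simulate_bulk
from mcpmap.io_ontology import CohortViews
from mcpmap.mcp_factor import build_views, fit_mcp
from mcpmap.normalization_de import differential_expression
from mcpmap.disease_scoring import disease_score
from mcpmap._stats import auroc

cfg = SimConfig(n_studies=2, samples_per_arm=15, n_genes=600, seed=7)
cohort = simulate_cohort(cfg)

ds = build_views(CohortViews.from_cohort(cohort))
model = fit_mcp(ds, n_factors=5)
labels = cohort.metadata.loc[model.scores.index, "disease"]
best = max(model.scores, key=lambda k: auroc(model.scores[k], labels, "HF"))
print(f"disease factor: {best}  AUROC {auroc(model.scores[best], labels, 'HF'):.3f}")
print(f"median R2 across cell types: {model.r2[best].median():.3f}")
r = np.corrcoef(model.scores[best],
                cohort.truth.factor_scores.loc[model.scores.index])[0, 1]
print(f"correlation with planted program: {r:.3f}")

bulk, _ = simulate_bulk(cohort, noise_sd=0.1, seed=8)
meta = cohort.metadata
a = meta.index[meta["study"] == "study0"]
b = meta.index[meta["study"] == "study1"]
sig = differential_expression(np.log2(bulk[a] + 1), meta.loc[a, "disease"])
res = disease_score(np.log2(bulk[b] + 1), sig, top_n=500,
                    labels=meta.loc[b, "disease"])
print(f"study0 -> study1 disease-score AUROC: {res.auroc:.3f} "
      f"({res.n_genes_used} genes)")
```

prints

```
disease factor: MCP1  AUROC 0.857
median R2 across cell types: 0.159
correlation with planted program: 0.999
study0 -> study1 disease-score AUROC: 0.911 (500 genes)
```

The first factor is the planted disease program (correlation 0.999 with
the generator's latent factor); its AUROC of 0.857 sits at the ceiling
implied by the planted 1.5-SD disease shift. The bulk disease score
transfers across studies at AUROC 0.911 because bulk mixtures carry the
compositional disease signal on top of the molecular program.

A thin CLI wraps the tool-like steps:

```bash
mcpmap simulate --config cfg.yaml --out cohort/ --seed 3
mcpmap markers --views cohort/ --out markers.gmt
mcpmap score --ref sigA.tsv --test exprB.tsv --labels meta.tsv --out scores.tsv
mcpmap deconv --bulk bulk.tsv --signature sig.tsv --out props.tsv
```

## Layout

```
src/mcpmap/
  cohort_synth.py        synthetic multi-study cohorts with ground truth
  io_ontology.py         harmonization, pseudobulking, contamination QC
  normalization_de.py    TMM, log-CPM, moderated-t DE, markers, Fisher meta
  disease_scoring.py     disease scores, AUROC, GSEA-style enrichment
  composition_analysis.py  clr, compositional signatures/scores, LMMs
  mcp_factor.py          filter cascade + masked ALS factor model
  project_classify.py    pseudoinverse projection, LDA, logistic boundary
  enrichment_core.py     ulm scoring, hypergeometric ORA, programs, vectors
  coordination_comm.py   coordination networks, ligand-receptor, AUPR
  tissue_deconv.py       deregulation annotation, NNLS deconvolution
  labor_division.py      semi-partial R2 and labor classes
  workflows.py           end-to-end benchmark workflows
  lmm.py                 profiled-REML random-intercept engine
```

See `docs/methods.md` for the modeling choices and their rationale.
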