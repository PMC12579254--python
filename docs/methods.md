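# Methods

This note documents the models implemented in `mcpmap`, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## The synthetic cohort generator

`cohort_synth.simulate_cohort` emulates a multi-study single-nucleus
heart-failure compendium. For gene *g*, cell type *k*, sample *i*:

```
log rate  eta_gki = baseline_g + marker block + f_i * w_gk + batch(study_i, k, g)
counts    ~ Gamma-Poisson(mean = libfactor * exp(eta), variance = m + phi m^2)
```

- `baseline_g ~ N(log 60, 1)` on the natural-log scale, giving
  pseudobulk-like count depths.
- **Markers**: each of the 7 cell types gets a disjoint block of
  `n_markers_per_type` genes raised `marker_log2fc = 3` log2 units in its
  own view. A fraction `marker_program_frac = 0.3` of each type's markers
  additionally carries a program loading in its own view — these are the
  *molecularly deregulated markers*; those of shrinking cell types are
  forced positive and recorded as NPPA-like (up-regulated despite a
  compositional decrease), mirroring the observed share of
  disease-deregulated marker genes.
- **The planted program**: a latent factor
  `f_i = mcp_effect * 1{HF} + N(0,1)`, standardized to unit variance
  within study so `mcp_effect` is in SD units (default 1.5). Loadings
  `w_gk` are drawn for per-view subsets of a shared 120-gene pool
  (magnitude U(0.5, 1), mixed signs), so program genes overlap across
  views — the multicellular structure downstream modules must recover.
  Note the factor contract caps the achievable per-factor disease AUROC
  at `Phi(mcp_effect / sqrt 2)` (0.856 at the default), which is the
  ceiling the factor-model benchmarks report against.
- **Batch**: per (study, view, gene) offsets `N(0, batch_sd)` with
  `batch_sd = 0.5` natural-log units — strong enough that single-study
  marker calls wobble and cross-study consensus is genuinely needed.
- **Compositions**: Dirichlet draws with concentration
  `(14, 10, 9, 4, 3, 5, 4)` (CM-dominated tissue); under disease the
  concentrations are multiplied by `exp(comp_shift)` with default shifts
  `(-0.5, 0, +0.2, -0.4, -0.2, +0.3, +0.6)` — every type but the
  fibroblasts changes, cardiomyocytes and pericytes shrink, lymphoid
  cells expand most. Realized per-sample cell counts are multinomial
  (1500 cells), and pseudobulk profiles exist only where cells exist.
- **Ambient contamination**: after drawing counts, each profile is
  convex-mixed with the cell-count-weighted pooled expected profile: a
  binomial thinning at `1 - rho` plus a Poisson ambient component, so the
  expected profile is exactly `(1-rho)*own + rho*pooled` and counts stay
  integers. `ambient_rho = 0.05` by default; the contamination QC score
  is strictly increasing in it.
- **Covariates** (sex, age, etiology) are generated independent of the
  program, giving exact nulls for calibration tests.

`simulate_bulk` mixes each cell type's expected (noise-free) profile,
scaled to a common library of 1e6, by the sample's true composition,
with per-gene log-normal noise. `simulate_fibro_states` generates
patient × state pseudobulks with four planted gene classes (specialist:
state offsets `N(0, 0.8)`; generalist: disease shift ±0.8; acquired
generalist: both; residual SD 0.3) — effect sizes chosen so the planted
semi-partial R² clears or undershoots the 0.1 threshold with margin.
`simulate_ligand_prior` plants true ligands whose prior potential
concentrates on the receiver view's most-loaded genes, with uniform
decoys.

What the generator does **not** emulate: droplet chemistry and doublets,
spatial structure, nonlinear or time-dependent programs, study-level
composition batch effects, and correlated covariates. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated generative assumptions, not robustness to every artifact of
real single-nucleus data.

## Normalization and differential expression

TMM follows the published algorithm: reference column by 75th-percentile
count share closest to the mean, M values trimmed 30% and A values 5%
two-sided by rank, inverse-delta-method precision weights, factors
normalized to geometric mean 1. log-CPM is
`log2((count + prior) / (lib * factor) * 1e6)` with prior 0.5.

The moderated-t contrast fits per-gene OLS (intercept, group indicator,
optional covariates) and shrinks residual variances toward their mean:
`s~² = (d0 s0² + d s²)/(d0 + d)` with prior df `d0 = 4` and
`s0² = mean(s²)`; t is referred to `d0 + d` df. `d0 = 0` recovers the
pooled-variance t-test exactly (tested). This is a deliberately simple
empirical-Bayes surrogate for limma's full hierarchy (no abundance
trend); the marker thresholds (log2FC > 2, FDR < 0.01) operate on it
unchanged. Consensus markers combine per-study one-vs-rest FDRs by
Fisher's method over genes measured in ≥3 studies, gated by mean
log2FC > 2 — per-study batch noise wobbles single-study marker calls,
and the consensus restores Jaccard ≈ 1 against the planted sets.

Fisher p-values of 0 are clipped at 1e-300 with a warning. Top-n
selections break p-value ties by |t| descending, then gene id.

## Disease scores

Genes are z-scored across the *test* study's samples (cases and
controls; the all-sample convention), then combined with the reference
t-vector over the reference's top-500 genes by p. The score is invariant
to per-gene affine rescaling of the test matrix. The compositional
variant z-scores per-type clr values the same way. AUROC is the
Mann–Whitney U statistic with midranks. Directional enrichment is the
weighted Kolmogorov–Smirnov running sum with exponent 1 on |statistic|
(exponent 0 available).

## The factor model

Views are filtered in order: pseudobulk profiles from <20 cells; views
present in <40% of samples or with ≤50 genes; genes never reaching 20
counts in any sample or detected in <40% of samples; markers of *other*
cell types; samples detecting <97% of the view's genes. Each (study,
view) block is TMM + log-CPM normalized separately, then centered per
study and gene (group-wise centering) and scaled `1/sqrt(p_v)` so large
views do not dominate.

The factorization minimizes the masked squared error by alternating
least squares: loadings per view over the view's observed samples,
scores per sample over its observed views (samples grouped by
observed-view pattern for batched solves). Initialization is the SVD of
the zero-imputed concatenated matrix — no randomness anywhere, so fits
are bit-reproducible. Convergence: relative objective decrease below
1e-6 (typically ~20 iterations at cohort scale). Factor scores are
rescaled to unit variance (scale absorbed into loadings) so the |w| ≥
0.1 enrichment floor has a stable meaning; factors are ordered by total
R² and oriented positive toward HF (largest-|loading| gene positive when
no labels exist).

Two identifiability caveats, both verified in tests: (i) the objective
is rotation-invariant, so individual factors are only identified when
their variances differ — on the study cohorts the planted program
dominates and is recovered at correlation ≈ 0.999; (ii) with missing
views, per-view centering over observed samples makes exactly-rank-K
data slightly off-rank (a rank-1 mean offset per view); one extra
factor absorbs it.

Variance explained is computed per factor and view on the centered data;
covariate association uses one-way ANOVA (categorical) or simple
regression (continuous), with an optional study-random-intercept
variant, BH across tests; a covariate's total explained variance sums R²
over its significantly associated factors.

## Projection and classifiers

External cohorts are normalized the same way, centered on their own
feature means (the stated convention; training-mean centering is a
flag), restricted to the genes shared with the model (dropped, not
zero-filled, to avoid asymmetric shrinkage), view-scaled, and multiplied
by the pseudoinverse of the concatenated loadings. Restricted
projections zero all other views' loadings. Cohorts without healthy
controls are standardized gene-wise against a healthy reference
(`(x - mean_ref)/sd_ref`; zero-variance genes dropped). LDA uses pooled
covariance (lsqr solver; shrinkage fallback on singularity); the
logistic boundary is a near-unpenalized fit with a penalized fallback
under separation.

## Mixed models

All random-intercept models run on an in-package profiled-REML engine:
the variance ratio `lambda = tau²/sigma²` is profiled out and optimized
in 1-D (bounded scalar search on log lambda), with the per-group
rank-one Woodbury inverse making each evaluation O(n). With two
intercepts (study + patient, for the labor models) the same profiling
runs in 2-D over a global Woodbury factorization of the indicator
columns. Estimates match statsmodels MixedLM to ~1e-5 and a dense
grid-search GLS oracle to 1e-6 on test instances. p-values are Wald
normal approximations — accurate at the group counts used here (≥4
studies, tens of samples), and the measured type-I error at nominal 0.05
is ≈ 0.05–0.06.

Semi-partial R² is the drop in marginal (fixed-effect, Nakagawa-style)
R² when a covariate is refit out, clipped at zero. This replaces the
Kenward–Roger-based R²β; the 0.1 classification thresholds are kept.
Because spurious R² scales like p/n, null calibration is run at the same
design scale as the analysis (4 studies × 20 patients × 6 states; null
mean ≈ 0.006).

## Coordination networks and ligand activity

Program signatures (per-view ulm enrichment of the factor loadings,
|w| ≥ 0.1) are z-scored **within study** before the network models.
This choice resolves an ambiguity: it makes edge weights exactly
invariant to study-constant signature offsets and scale differences,
keeps coefficients comparable across cell types, and leaves the study
random intercept to absorb residual structure. Edge weight =
standardized coefficient × conditional R² (marginal R² behind a flag);
edges with signed weight < 0.2 are dropped, with unfiltered importances
retained for network comparison (Spearman over the union; per-type
one-sample t on paired HF−NF differences, BH).

Ligand prioritization: targets are the top 10% most extreme receiver
loadings; background the 30% closest to zero; AUPR of the prior-ranked
target∪background list minus its prevalence (the random baseline) is
the corrected activity. Average precision is the step integral
`Σ (R_k − R_{k−1}) P_k`; its small positive finite-sample bias under
random rankings (~1/n_pos scale) is why null checks use ≥1000-gene
universes.

## Deregulation annotation and deconvolution

Compositional score: `Σ_{types marking g} mean-logFC(g, type) ×
mean-comp-t(type)` (unweighted means across studies; dual markers sum).
Molecular score: mean loading of the disease factor across the views
modeling the gene. Genes significant in the bulk consensus (BH-adjusted
Fisher p < 0.05) are classed by sign agreement: compositional only /
molecular only / both / unknown. The planted NPPA-like genes (bulk-up
markers of shrinking types) are always classed molecular — the
annotation's key fidelity property.

Deconvolution is non-negative least squares per sample on TPM-scale
signature matrices (columns sum to 1e6 before marker restriction),
built as three replicates each averaging a 30% sample of the healthy
(NF) reference, with predictions averaged. NNLS replaces the ν-SVR of
reference deconvolution tools: the benchmark compares *marker subsets*,
not engines, and NNLS is deterministic. On the 8-study benchmark,
signatures restricted to compositionally regulated markers outperform
molecularly deregulated markers (RMSE ≈ 0.07 vs ≈ 0.13, paired Wilcoxon
p < 0.01) — molecular markers violate the constant-signature assumption
under disease.

## Problem sizes

The benchmark workflows use: the reference cohort of 4 studies × 30
samples/arm × 1200 genes (disease transfer, factor model, composition,
markers); 50 replicates of 240-sample signature matrices (coordination);
4 studies × 20 patients × 6 states × 48 genes (labor); 8 studies × 12
samples/arm × 1000 genes with 40 markers/type (deconvolution benchmark,
where marker subsets must stay above the 25-gene deconvolution floor);
50 two-study null cohorts, 300 LMM null fits and 200 semi-partial null
fits (calibration). These sizes give Monte-Carlo error comfortably
inside every acceptance band while keeping a full run around a minute.

## Known limitations

- The moderated-t surrogate has no mean-variance trend; very low-count
  pseudobulks are better served by a count-model DE.
- Wald p-values undercover slightly at very small study counts (<4
  groups); Satterthwaite/Kenward–Roger corrections are not implemented.
- The ALS factorization has no sparsity prior (none is wanted here) and
  no automatic choice of K.
- The generator's composition model has no study-level composition batch
  effect, so the composition LMM's study variance share is near zero on
  synthetic cohorts (its estimation is still exercised by dedicated
  tests with constructed offsets).
- Ortholog mapping for cross-species projection is a one-to-one mapping
  table supplied by the user; curation is out of scope.
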