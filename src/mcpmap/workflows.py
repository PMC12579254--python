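"""End-to-end study workflows on synthetic cohorts.

Each function runs one complete arm of the analysis on generated data
with known ground truth and returns a flat dict of scalar summaries:
cross-study disease-score transfer, multicellular-program recovery with
leave-one-study-out projection and LDA transfer, compositional
mixed-model recovery, coordination-edge recovery, consensus-marker
recovery, division-of-labor classification, the deconvolution marker-
subset benchmark, and null-simulation calibration.  They are the
building blocks of the reproducibility script and of the simulation-
based test suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import auroc
from .cohort_synth import (
    SimConfig,
    simulate_bulk,
    simulate_cohort,
    simulate_fibro_states,
)
from .composition_analysis import (
    clr_transform,
    compositional_signature,
    lmm_composition,
)
from .coordination_comm import coordination_network
from .disease_scoring import disease_score
from .io_ontology import CohortViews
from .labor_division import labor_table
from .mcp_factor import build_views, fit_mcp
from .normalization_de import (
    consensus_markers,
    differential_expression,
    fisher_meta,
)
from .project_classify import predict_lda, project_samples, train_lda
from .tissue_deconv import (
    annotate_deregulation,
    benchmark_deconv,
    build_signature_matrix,
    compositional_score,
    deconvolve,
    molecular_score,
)

__all__ = [
    "default_cohort",
    "disease_transfer_benchmark",
    "mcp_benchmark",
    "composition_benchmark",
    "coordination_benchmark",
    "marker_benchmark",
    "labor_benchmark",
    "deconvolution_benchmark",
    "calibration_suite",
]


def default_cohort(seed: int, **overrides):
    """The reference synthetic cohort: 4 studies, 30 samples per arm."""
    cfg = SimConfig(seed=seed, **overrides)
    return simulate_cohort(cfg)


def _per_study_bulk_signatures(cohort, bulk, top_n=500):
    meta = cohort.metadata
    studies = list(meta["study"].unique())
    exprs, sigs = {}, {}
    for st in studies:
        cols = meta.index[meta["study"] == st]
        expr = np.log2(bulk[cols] + 1.0)
        exprs[st] = expr
        sigs[st] = differential_expression(
            expr, meta.loc[cols, "disease"], positive_class="HF", study=st)
    return studies, exprs, sigs


def disease_transfer_benchmark(cohort, seed: int, noise_sd: float = 0.1,
                               top_n: int = 500) -> dict:
    """Cross-study bulk disease-score AUROC over all reference/test pairs."""
    bulk, _ = simulate_bulk(cohort, noise_sd=noise_sd, seed=seed)
    studies, exprs, sigs = _per_study_bulk_signatures(cohort, bulk, top_n)
    meta = cohort.metadata
    aucs = []
    for ref in studies:
        for test in studies:
            if ref == test:
                continue
            cols = meta.index[meta["study"] == test]
            res = disease_score(exprs[test], sigs[ref], top_n=top_n,
                                labels=meta.loc[cols, "disease"])
            aucs.append(res.auroc)
    return {"cross_study_disease_auroc_mean": float(np.mean(aucs)),
            "cross_study_disease_auroc_min": float(np.min(aucs)),
            "n_study_pairs": len(aucs)}


def mcp_benchmark(cohort, n_factors: int = 10) -> dict:
    """Fit the factor model; score disease separation, truth recovery and
    leave-one-study-out LDA transfer through pseudoinverse projection."""
    meta = cohort.metadata
    ds = build_views(CohortViews.from_cohort(cohort))
    model = fit_mcp(ds, n_factors=n_factors)
    labels = meta.loc[model.scores.index, "disease"]
    per_factor_auc = {k: auroc(model.scores[k], labels, "HF")
                      for k in model.scores.columns}
    best_factor = max(per_factor_auc, key=per_factor_auc.get)
    truth_f = cohort.truth.factor_scores.loc[model.scores.index]
    best_corr = max(abs(np.corrcoef(model.scores[k], truth_f)[0, 1])
                    for k in model.scores.columns)

    # leave-one-study-out: fit on the rest, project the held-out study
    studies = list(meta["study"].unique())
    lda_aucs = []
    for held in studies:
        train_keys = {k: v for k, v in cohort.views.items() if k[0] != held}
        held_keys = {k: v for k, v in cohort.views.items() if k[0] == held}
        train_cv = CohortViews(
            views=train_keys,
            metadata=meta[meta["study"] != held].copy(),
            qc=cohort.qc[cohort.qc["sample"].isin(
                meta.index[meta["study"] != held])].copy())
        held_cv = CohortViews(
            views=held_keys,
            metadata=meta[meta["study"] == held].copy(),
            qc=cohort.qc[cohort.qc["sample"].isin(
                meta.index[meta["study"] == held])].copy())
        ds_tr = build_views(train_cv)
        m = fit_mcp(ds_tr, n_factors=n_factors)
        ds_te = build_views(held_cv)
        proj = project_samples(m, ds_te.views)
        clf = train_lda(m.scores, meta.loc[m.scores.index, "disease"])
        _, a = predict_lda(clf, proj.scores,
                           meta.loc[proj.scores.index, "disease"])
        lda_aucs.append(a)
    return {"mcp_best_factor_auroc": float(per_factor_auc[best_factor]),
            "mcp_truth_correlation": float(best_corr),
            "lda_cross_study_auroc_mean": float(np.mean(lda_aucs)),
            "disease_factor": best_factor,
            "n_factors": n_factors}


def composition_benchmark(cohort) -> dict:
    """Mixed-model recovery of the planted composition shift signs."""
    comp = cohort.truth.compositions
    clr = clr_transform(comp)
    meta = cohort.metadata.loc[comp.index]
    table = lmm_composition(clr, meta["disease"], meta["study"])
    shifts = cohort.truth.comp_shift
    planted = {ct: s for ct, s in shifts.items() if s != 0}
    correct = sum(
        np.sign(table.loc[ct, "estimate"]) == np.sign(s)
        for ct, s in planted.items())
    sig_correct = sum(
        (np.sign(table.loc[ct, "estimate"]) == np.sign(s))
        and table.loc[ct, "adj_p"] < 0.05
        for ct, s in planted.items())
    return {"composition_sign_recovery": correct / len(planted),
            "composition_sign_recovery_significant": sig_correct / len(planted),
            "study_var_prop_mean": float(table["study_var_prop"].mean()),
            "n_shifted_types": len(planted)}


def coordination_benchmark(seed: int, n_reps: int = 50, n: int = 240,
                           n_studies: int = 4, coef: float = 0.8,
                           noise: float = 0.5) -> dict:
    """Recovery of a planted Fib->CM coordination edge across replicates."""
    rng = np.random.default_rng(seed)
    celltypes = ["CM", "Fib", "Endo", "PC", "vSMC", "Myeloid", "Lymphoid"]
    hits = 0
    for _ in range(n_reps):
        study = np.repeat([f"study{i}" for i in range(n_studies)],
                          n // n_studies)
        S = pd.DataFrame(rng.normal(size=(n, len(celltypes))),
                         columns=celltypes,
                         index=[f"s{i}" for i in range(n)])
        S["CM"] = coef * S["Fib"] + noise * rng.normal(size=n)
        offs = rng.normal(0, 0.5, n_studies)
        S = S.add(offs[pd.factorize(study)[0]], axis=0)
        net = coordination_network(S, study)
        if net.importances["CM"].abs().idxmax() == "Fib":
            hits += 1
    return {"coordination_edge_recovery_rate": hits / n_reps,
            "n_replicates": n_reps}


def marker_benchmark(cohort, min_studies: int = 3) -> dict:
    """Jaccard agreement of consensus markers with the planted sets."""
    by_study: dict = {}
    for (s, ct), m in cohort.views.items():
        by_study.setdefault(s, {})[ct] = m
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sets, _ = consensus_markers(by_study, min_studies=min_studies)
    jacs = {}
    for ct, truth in cohort.truth.marker_sets.items():
        got = sets.get(ct, set())
        union = got | truth
        jacs[ct] = len(got & truth) / len(union) if union else 0.0
    return {"marker_jaccard_mean": float(np.mean(list(jacs.values()))),
            "marker_jaccard_min": float(np.min(list(jacs.values()))),
            "n_celltypes": len(jacs)}


def labor_benchmark(seed: int, n_studies: int = 4, samples_per_arm: int = 10,
                    n_states: int = 6, n_genes_per_class: int = 12) -> dict:
    """Balanced accuracy of division-of-labor class recovery."""
    cfg = SimConfig(n_studies=n_studies, samples_per_arm=samples_per_arm,
                    seed=seed)
    sim = simulate_fibro_states(cfg, n_states=n_states,
                                n_genes_per_class=n_genes_per_class,
                                seed=seed + 1)
    table = labor_table(sim.expr, sim.meta)
    truth = sim.labor_truth.loc[table.index]
    recalls = []
    for cls in truth.unique():
        mask = truth == cls
        recalls.append((table.loc[mask, "label"] == cls).mean())
    return {"labor_balanced_accuracy": float(np.mean(recalls)),
            "n_genes": len(table), "n_classes": len(recalls)}


def deconvolution_benchmark(seed: int, n_studies: int = 8,
                            samples_per_arm: int = 12, n_genes: int = 1000,
                            n_markers_per_type: int = 40,
                            noise_sd: float = 0.1) -> dict:
    """Marker-subset deconvolution benchmark with deregulation annotation.

    Runs the full chain on an 8-study cohort: consensus markers, bulk
    consensus signature, compositional and molecular deregulation scores,
    sign-agreement annotation (checking that planted NPPA-like genes are
    called molecular), then NNLS deconvolution of the bulk mixtures with
    signature matrices restricted to compositionally vs molecularly
    deregulated markers, compared by paired Wilcoxon on per-study RMSE.
    """
    import warnings

    cfg = SimConfig(n_studies=n_studies, samples_per_arm=samples_per_arm,
                    n_genes=n_genes, n_markers_per_type=n_markers_per_type,
                    seed=seed)
    cohort = simulate_cohort(cfg)
    meta = cohort.metadata
    bulk, true_props = simulate_bulk(cohort, noise_sd=noise_sd, seed=seed + 1)

    by_study: dict = {}
    for (s, ct), m in cohort.views.items():
        by_study.setdefault(s, {})[ct] = m
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        marker_sets, marker_rankings = consensus_markers(by_study,
                                                         min_studies=3)

        # bulk consensus signature across studies
        studies, exprs, sigs = _per_study_bulk_signatures(cohort, bulk)
        P = pd.DataFrame({st: sigs[st].table["p"] for st in studies})
        L = pd.DataFrame({st: sigs[st].table["logFC"] for st in studies})
        bulk_consensus = fisher_meta(P, min_studies=max(3, n_studies // 2),
                                     logfc_matrix=L).table

    # compositional signature: mean clr t across studies
    comp = cohort.truth.compositions
    clr = clr_transform(comp)
    t_cols = {}
    for st in studies:
        idx = meta.index[meta["study"] == st]
        t_cols[st] = compositional_signature(clr.loc[idx],
                                             meta.loc[idx, "disease"])["t"]
    comp_t = pd.DataFrame(t_cols).mean(axis=1)

    # per-marker mean one-vs-rest logFC across studies
    lfc = pd.DataFrame(np.nan, index=bulk_consensus.index,
                       columns=list(marker_sets))
    for ct, ranking in marker_rankings.items():
        genes = [g for g in marker_sets[ct] if g in lfc.index]
        lfc.loc[genes, ct] = ranking.table.loc[genes, "mean_logfc"]

    comp_scores = compositional_score(lfc, comp_t)

    ds = build_views(CohortViews.from_cohort(cohort),
                     markers_by_type=marker_sets)
    model = fit_mcp(ds, n_factors=10)
    disease_factor = model.disease_factors(meta, n=1)[0]
    mol_scores = molecular_score(model, disease_factor)

    annotation = annotate_deregulation(bulk_consensus, comp_scores, mol_scores)
    tab = annotation.table
    nppa = [g for g in cohort.truth.nppa_like if g in tab.index]
    nppa_mol = (float((tab.loc[nppa, "label"] == "molecular").mean())
                if nppa else np.nan)

    all_markers = set().union(*marker_sets.values())
    comp_markers = set(tab.index[tab["label"].isin(
        ["compositional", "compositional_and_molecular"])]) & all_markers
    mol_markers = set(tab.index[tab["label"] == "molecular"]) & all_markers

    # healthy reference: NF pseudobulk columns pooled across studies
    reference_views = {}
    for ct in sorted({ct for _, ct in cohort.views}):
        mats = []
        for (s, c), m in cohort.views.items():
            if c != ct:
                continue
            nf_cols = [col for col in m.columns
                       if meta.loc[col, "disease"] == "NF"]
            mats.append(m[nf_cols])
        reference_views[ct] = pd.concat(mats, axis=1)

    rmse = {}
    for name, subset in (("compositional", comp_markers),
                         ("molecular", mol_markers)):
        sig_mats = build_signature_matrix(reference_views, subset,
                                          n_replicates=3, seed=seed + 2)
        est = deconvolve(bulk, sig_mats)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics, _ = benchmark_deconv(
                est, true_props, meta.loc[true_props.index, "study"],
                meta.loc[true_props.index, "disease"])
        rmse[name] = metrics["rmse"]
    wil = stats.wilcoxon(rmse["compositional"], rmse["molecular"],
                         alternative="less")
    fractions = annotation.fractions
    return {
        "nppa_molecular_fraction": nppa_mol,
        "rmse_compositional_markers_mean": float(rmse["compositional"].mean()),
        "rmse_molecular_markers_mean": float(rmse["molecular"].mean()),
        "deconv_wilcoxon_p": float(wil.pvalue),
        "n_compositional_markers": len(comp_markers),
        "n_molecular_markers": len(mol_markers),
        "fraction_compositional": float(fractions["compositional"]),
        "fraction_molecular": float(fractions["molecular"]),
        "fraction_comp_and_mol": float(
            fractions["compositional_and_molecular"]),
        "fraction_unknown": float(fractions["unknown"]),
        "n_studies": n_studies,
    }


def calibration_suite(seed: int, n_null_cohorts: int = 50,
                      n_lmm_reps: int = 300,
                      n_semipartial_reps: int = 200) -> dict:
    """Null-simulation calibration of the inferential machinery."""
    rng = np.random.default_rng(seed)

    # DE p-values under permuted labels
    Y = pd.DataFrame(rng.normal(size=(3000, 40)))
    labels = np.array(["HF"] * 20 + ["NF"] * 20)
    perm = rng.permutation(labels)
    de = differential_expression(Y, perm)
    de_ks = stats.kstest(de.table["p"], "uniform").pvalue

    # ANOVA p under permuted class labels
    scores = rng.normal(size=200)
    anova_ps = []
    for _ in range(500):
        pl = rng.permutation(np.repeat(["HF", "NF"], 100))
        anova_ps.append(stats.f_oneway(scores[pl == "HF"],
                                       scores[pl == "NF"]).pvalue)
    anova_ks = stats.kstest(anova_ps, "uniform").pvalue

    # composition LMM type-I error under a study-structured null
    from .lmm import fit_random_intercept

    rejections = 0
    n_studies, n = 4, 30
    for _ in range(n_lmm_reps):
        study = np.repeat(np.arange(n_studies), n)
        hf = np.tile(np.r_[np.ones(n // 2), np.zeros(n // 2)], n_studies)
        y = rng.normal(0, 0.7, n_studies)[study] + rng.normal(0, 1, len(study))
        X = np.column_stack([np.ones(len(y)), hf])
        res = fit_random_intercept(y, X, study)
        if res.pvalues[1] < 0.05:
            rejections += 1
    lmm_type1 = rejections / n_lmm_reps

    # cross-study disease-score AUROC under a null generator
    null_aucs = []
    for rep in range(n_null_cohorts):
        cfg = SimConfig(n_studies=2, samples_per_arm=15, n_genes=300,
                        n_markers_per_type=10, mcp_effect=0.0,
                        comp_shift=(0.0,) * 7,
                        seed=int(rng.integers(2**31 - 1)))
        cohort = simulate_cohort(cfg)
        bulk, _ = simulate_bulk(cohort, noise_sd=0.1,
                                seed=int(rng.integers(2**31 - 1)))
        studies, exprs, sigs = _per_study_bulk_signatures(cohort, bulk)
        meta = cohort.metadata
        cols = meta.index[meta["study"] == studies[1]]
        res = disease_score(exprs[studies[1]], sigs[studies[0]], top_n=500,
                            labels=meta.loc[cols, "disease"])
        null_aucs.append(res.auroc)

    # semi-partial R2 under the null
    from .labor_division import lmm_semipartial

    # null run at the same design scale as the labor analysis itself:
    # spurious semi-partial R2 scales like p/n, so the calibration must
    # use the analysis design (4 studies x 20 patients x 6 states)
    sp_vals = []
    n_st, n_pat, n_state = 4, 20, 6
    study = np.repeat(np.arange(n_st), n_pat * n_state)
    pat = np.repeat(np.arange(n_st * n_pat), n_state)
    state = np.tile(np.arange(n_state), n_st * n_pat)
    hf = (pat % 2).astype(float)
    for _ in range(n_semipartial_reps):
        y = rng.normal(size=len(hf))
        sp = lmm_semipartial(y, hf, state, study, pat)
        sp_vals.append([sp["r2_hf"], sp["r2_cs"]])
    return {
        "de_null_ks_p": float(de_ks),
        "anova_null_ks_p": float(anova_ks),
        "lmm_type1_error": float(lmm_type1),
        "null_auroc_mean": float(np.mean(null_aucs)),
        "semipartial_null_mean": float(np.mean(sp_vals)),
    }
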