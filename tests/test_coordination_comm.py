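"""Coordination networks, network comparison, ligand-receptor scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mcpmap._stats import average_precision
from mcpmap.coordination_comm import (
    compare_networks,
    coordination_network,
    lr_scores,
    prioritize_ligands,
    signature_matrix,
)


def make_signatures(rng, n=200, n_studies=4, chain=None, noise=0.3):
    """Sample x cell-type signature matrix with optional planted chain
    (target, source, coefficient) plus study offsets."""
    celltypes = ["CM", "Fib", "Endo", "PC", "vSMC", "Myeloid", "Lymphoid"]
    study = np.repeat([f"study{i}" for i in range(n_studies)],
                      n // n_studies)
    S = pd.DataFrame(rng.normal(size=(n, len(celltypes))), columns=celltypes)
    if chain is not None:
        target, source, coef = chain
        S[target] = coef * S[source] + noise * rng.normal(size=n)
    offs = {f"study{i}": rng.normal(0, 0.5) for i in range(n_studies)}
    S = S.add(pd.Series(study).map(offs).to_numpy(), axis=0)
    S.index = [f"s{i}" for i in range(n)]
    return S, study


class TestSignatureMatrix:
    def test_sample_matching_loadings_scores_highest(self, rng):
        genes = [f"g{i}" for i in range(40)]
        w = pd.Series(rng.normal(size=40), index=genes)

        class Model:
            loadings = {"CM": pd.DataFrame({"MCP1": w})}

        expr = pd.DataFrame(rng.normal(size=(40, 5)), index=genes,
                            columns=[f"s{i}" for i in range(5)])
        expr["aligned"] = 2.0 * w
        out = signature_matrix(Model(), {"CM": expr}, "MCP1")
        assert out["CM"].idxmax() == "aligned"

    def test_missing_view_propagates_as_nan(self, rng):
        genes = [f"g{i}" for i in range(30)]
        w = pd.Series(rng.normal(size=30), index=genes)

        class Model:
            loadings = {"CM": pd.DataFrame({"MCP1": w}),
                        "Fib": pd.DataFrame({"MCP1": w})}

        views = {"CM": pd.DataFrame(rng.normal(size=(30, 4)), index=genes,
                                    columns=list("abcd")),
                 "Fib": pd.DataFrame(rng.normal(size=(30, 2)), index=genes,
                                     columns=list("ab"))}
        out = signature_matrix(Model(), views, "MCP1")
        assert np.isnan(out.loc["c", "Fib"])
        assert not np.isnan(out.loc["c", "CM"])


class TestCoordinationNetwork:
    def test_perfect_dependence_gives_unit_edge(self, rng):
        S, study = make_signatures(rng, chain=("CM", "Fib", 1.0), noise=0.01)
        net = coordination_network(S, study, condition="all")
        w = net.edge_weight("Fib", "CM")
        assert w is not None and w > 0.9
        others = net.edges[(net.edges["target"] == "CM")
                           & (net.edges["sender"] != "Fib")]
        assert (others["weight"].abs() < 0.2).all() or others.empty

    def test_subthreshold_edges_filtered(self, rng):
        # coefficient ~0.4 with weak fit -> weight below 0.2 is dropped
        S, study = make_signatures(rng, chain=("CM", "Fib", 0.4), noise=2.0)
        net = coordination_network(S, study)
        assert (net.edges["weight"] >= 0.2).all()
        # the unfiltered importance is still recorded
        assert np.isfinite(net.importances.loc["Fib", "CM"])

    def test_study_constant_offsets_do_not_create_edges(self, rng):
        S, study = make_signatures(rng, chain=None)
        net_plain = coordination_network(S, study)
        shifted = S.add(pd.Series(study).map(
            {f"study{i}": 3.0 * i for i in range(4)}).to_numpy(), axis=0)
        net_shift = coordination_network(shifted, study)
        diff = (net_plain.importances - net_shift.importances).abs()
        assert np.nanmax(diff.to_numpy()) < 0.05

    def test_requires_multiple_studies(self, rng):
        S, _ = make_signatures(rng)
        with pytest.raises(ValueError):
            coordination_network(S, np.repeat("study0", len(S)))

    def test_planted_chain_is_dominant_incoming_edge(self, rng):
        hits = 0
        for rep in range(50):
            S, study = make_signatures(rng, n=240, chain=("CM", "Fib", 0.8),
                                       noise=0.5)
            net = coordination_network(S, study)
            inc = net.importances["CM"].abs()
            if inc.idxmax() == "Fib":
                hits += 1
        assert hits >= 45  # >= 90% of 50 replicates


class TestCompareNetworks:
    def test_identical_networks(self, rng):
        S, study = make_signatures(rng, chain=("CM", "Fib", 0.8))
        net = coordination_network(S, study)
        rho, p, shifts = compare_networks(net, net)
        assert rho == pytest.approx(1.0)
        assert (shifts["p"] == 1.0).all()

    def test_hand_computed_spearman(self):
        # two 3-node networks with known importances, no ties
        cts = ["A", "B", "C", "D"]
        ia = pd.DataFrame(np.nan, index=cts, columns=cts)
        ib = pd.DataFrame(np.nan, index=cts, columns=cts)
        vals_a = [0.1, 0.9, 0.3, 0.7, 0.5]
        vals_b = [0.2, 0.8, 0.1, 0.9, 0.4]
        cells = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"), ("D", "A")]
        for (s, t), va, vb in zip(cells, vals_a, vals_b):
            ia.loc[s, t] = va
            ib.loc[s, t] = vb

        class Net:
            def __init__(self, imp):
                self.importances = imp

        rho, _, _ = compare_networks(Net(ia), Net(ib))
        # ranks a: 1 5 2 4 3 ; ranks b: 2 4 1 5 3 -> d = (1,-1,-1,1,0)
        rho_hand = 1 - 6 * 4 / (5 * 24)
        assert rho == pytest.approx(rho_hand, rel=1e-12)

    def test_shuffled_weights_decorrelate(self, rng):
        S, study = make_signatures(rng, chain=("CM", "Fib", 0.8))
        net_a = coordination_network(S, study)
        rhos = []
        for _ in range(30):
            imp = net_a.importances.copy()
            vals = imp.to_numpy().ravel()
            ok = ~np.isnan(vals)
            shuffled = vals.copy()
            shuffled[ok] = rng.permutation(vals[ok])
            imp_b = pd.DataFrame(shuffled.reshape(imp.shape),
                                 index=imp.index, columns=imp.columns)

            class Net:
                importances = imp_b

            rho, _, _ = compare_networks(net_a, Net())
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1


class TestLRScores:
    def _model(self):
        genes = ["LigA", "LigB", "RecA", "RecB", "x"]

        class Model:
            loadings = {
                "Fib": pd.DataFrame({"MCP1": [0.3, 0.05, 0.0, 0.5, 0.2]},
                                    index=genes),
                "CM": pd.DataFrame({"MCP1": [0.0, 0.4, 0.25, 0.02, 0.1]},
                                   index=genes),
            }

        return Model()

    def test_scores_sum_both_loadings(self):
        lr = pd.DataFrame({"ligand": ["LigA"], "receptor": ["RecA"]})
        out = lr_scores(self._model(), "MCP1", lr)
        row = out[(out["sender"] == "Fib") & (out["receiver"] == "CM")].iloc[0]
        assert row["score"] == pytest.approx(0.3 + 0.25)

    def test_subthreshold_loadings_excluded(self):
        lr = pd.DataFrame({"ligand": ["LigB"], "receptor": ["RecA"]})
        out = lr_scores(self._model(), "MCP1", lr)
        # LigB has loading 0.05 in Fib -> Fib cannot send LigB
        assert out[(out["sender"] == "Fib")].empty
        # but CM (loading 0.4) can send it nowhere useful: receiver Fib has
        # RecA loading 0.0 -> excluded as well
        assert out[(out["sender"] == "CM") & (out["receiver"] == "Fib")].empty


class TestPrioritizeLigands:
    def test_perfect_ranking_gives_one_minus_prevalence(self, rng):
        genes = [f"g{i}" for i in range(200)]
        recv = pd.Series(np.linspace(2, -2, 200), index=genes)
        n_top = int(np.ceil(0.10 * 200))
        by_extreme = recv.abs().sort_values(ascending=False)
        targets = list(by_extreme.index[:n_top])
        send = pd.Series({"LigA": 0.5})
        pot = pd.Series(0.01, index=genes)
        pot[targets] = np.linspace(1.0, 0.9, len(targets))
        prior = pd.DataFrame([pot], index=["LigA"])
        out = prioritize_ligands(send, recv, prior)
        row = out.iloc[0]
        assert row["aupr"] == pytest.approx(1.0)
        assert row["corrected_aupr"] == pytest.approx(1.0 - row["prevalence"])
        # target set size is ceil(10% of the gene universe)
        assert row["prevalence"] == pytest.approx(
            n_top / (n_top + int(np.ceil(0.30 * 200))), abs=0.01)

    def test_random_potentials_average_to_zero(self, rng):
        # a gene universe large enough that the finite-sample positive
        # bias of average precision is inside the tolerance band
        G = 1000
        genes = [f"g{i}" for i in range(G)]
        recv = pd.Series(rng.normal(size=G), index=genes)
        send = pd.Series({"LigA": 0.5})
        vals = []
        for _ in range(200):
            prior = pd.DataFrame(rng.uniform(size=(1, G)), index=["LigA"],
                                 columns=genes)
            out = prioritize_ligands(send, recv, prior)
            vals.append(out["corrected_aupr"].iloc[0])
        assert abs(np.mean(vals)) < 0.02

    def test_unexpressed_ligands_skipped(self, rng):
        genes = [f"g{i}" for i in range(100)]
        recv = pd.Series(rng.normal(size=100), index=genes)
        send = pd.Series({"LigA": 0.05})
        prior = pd.DataFrame(rng.uniform(size=(1, 100)), index=["LigA"],
                             columns=genes)
        out = prioritize_ligands(send, recv, prior)
        assert out.empty


class TestAveragePrecision:
    def test_matches_all_thresholds_oracle(self, rng):
        def oracle(y, s):
            order = np.argsort(-s, kind="stable")
            y = np.asarray(y, float)[order]
            s = np.asarray(s)[order]
            ap, prev_rec = 0.0, 0.0
            npos = y.sum()
            for thr in np.unique(s)[::-1]:
                sel = s >= thr
                tp = y[sel].sum()
                prec = tp / sel.sum()
                rec = tp / npos
                ap += (rec - prev_rec) * prec
                prev_rec = rec
            return ap

        for _ in range(10):
            y = rng.integers(0, 2, size=30).astype(bool)
            if not y.any() or y.all():
                continue
            s = rng.integers(0, 8, size=30).astype(float)  # ties included
            assert average_precision(y, s) == pytest.approx(
                oracle(y, s), abs=1e-12)
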