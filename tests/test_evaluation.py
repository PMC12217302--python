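"""Mixed-model evaluation: MME vs dense GLS, REML likelihood and boundary
behaviour, selection indices, index accuracy."""

import warnings

import numpy as np
import pandas as pd
import pytest

from apisim.evaluation import (EBVTable, PerformanceFile, REMLWorkspace,
                               assemble_mme, index_accuracy, reml_estimate,
                               selection_index, solve_blup)
from apisim.pedigree import Pedigree, compute_A
from apisim.quantgen import GeneticParams, build_G


def small_population(rng, n_dams=6, kids_per_dam=2, missing_late=0.3):
    """Toy pedigree + random phenotypes: founders, one DPQ, daughters."""
    ped = Pedigree()
    recs = []
    entities = []
    for i in range(n_dams):
        q = ped.add_queen(None, None, node_id=f"F{i}")
        m = ped.add_open_mating(node_id=f"PSF{i}")
        w = ped.add_worker_group(q, m, node_id=f"WF{i}")
        entities.append((q, m, w))
    dpq = ped.add_queen(None, None, node_id="DPQ0")
    mdpq = ped.add_open_mating(node_id="PSD0")
    wdpq = ped.add_worker_group(dpq, mdpq, node_id="WD0")
    entities.append((dpq, mdpq, wdpq))
    for i, (q, m, w) in enumerate(entities[:n_dams]):
        for j in range(kids_per_dam):
            mate = ped.add_mating(dpq, node_id=f"M{i}_{j}")
            k = ped.add_queen(q, m, node_id=f"K{i}_{j}")
            wk = ped.add_worker_group(k, mate, node_id=f"WK{i}_{j}")
            entities.append((k, mate, wk))
    for cid, (q, m, w) in enumerate(entities):
        y2 = rng.normal() if rng.random() > missing_late else np.nan
        recs.append(dict(colony_id=f"C{cid}", queen_id=q, worker_group_id=w,
                         apiary=1 + cid % 2, year=2, y_T1=rng.normal(),
                         y_T2=y2))
    return ped, PerformanceFile(pd.DataFrame(recs)), entities


def dense_gls(ped, perf, G, R, system):
    """Dense GLS oracle in the exact layout of the assembled system."""
    st = compute_A(ped, include_worker_groups=False)
    assert st.ids == system.node_ids
    n_nodes = len(st.ids)
    pos = {n: p for p, n in enumerate(st.ids)}
    Gt = np.kron(G, st.A)
    df = perf.data
    obs = []
    for t in range(2):
        for r in range(len(df)):
            v = df[f"y_T{t + 1}"].iloc[r]
            if np.isfinite(v):
                obs.append((r, t, v))
    obs.sort(key=lambda o: (o[1], o[0]))
    nob = len(obs)
    Z = np.zeros((nob, 4 * n_nodes))
    X = np.zeros((nob, len(system.fixed_labels)))
    fl = {lab: j for j, lab in enumerate(system.fixed_labels)}
    y = np.zeros(nob)
    Rv = np.zeros((nob, nob))
    for a, (r, t, v) in enumerate(obs):
        wi = ped.index_of(df["worker_group_id"].iloc[r])
        q, m = ped.dam[wi], ped.sire[wi]
        Z[a, 2 * t * n_nodes + pos[ped.ids[q]]] = 0.5
        Z[a, 2 * t * n_nodes + pos[ped.ids[m]]] = 1.0
        Z[a, (2 * t + 1) * n_nodes + pos[ped.ids[q]]] = 1.0
        X[a, fl[(df["apiary"].iloc[r], df["year"].iloc[r], t)]] = 1.0
        y[a] = v
    for a, (r1, t1, _) in enumerate(obs):
        for b, (r2, t2, _) in enumerate(obs):
            if r1 == r2:
                Rv[a, b] = R[t1, t2]
    V = Z @ Gt @ Z.T + Rv
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = Gt @ Z.T @ Vi @ (y - X @ beta)
    return beta, u


class TestBLUP:
    def test_blup_equals_dense_gls_with_missing_late_records(self, rng):
        params = GeneticParams()
        G, R = build_G(params), params.residual_cov
        ped, perf, _ = small_population(rng)
        system = assemble_mme(perf, ped, G, R)
        table, sol = solve_blup(system, method="splu")
        beta, u = dense_gls(ped, perf, G, R, system)
        assert np.abs(sol[:system.n_fixed] - beta).max() < 1e-9
        assert np.abs(sol[system.n_fixed:] - u).max() < 1e-9

    def test_cg_matches_direct_solver(self, rng):
        params = GeneticParams()
        G, R = build_G(params), params.residual_cov
        ped, perf, _ = small_population(rng, n_dams=8, kids_per_dam=3)
        system = assemble_mme(perf, ped, G, R)
        _, direct = solve_blup(system, method="splu")
        _, iterative = solve_blup(system, method="cg")
        assert np.abs(direct - iterative).max() < 1e-6

    def test_single_record_shrinkage(self, rng):
        """One founder colony, no relatives: the summed EBV regresses the
        phenotype deviation by its reliability."""
        params = GeneticParams()
        G, R = build_G(params), params.residual_cov
        ped = Pedigree()
        q = ped.add_queen(None, None, node_id="F")
        m = ped.add_open_mating(node_id="PS")
        w = ped.add_worker_group(q, m, node_id="W")
        y = 2.0
        perf = PerformanceFile(pd.DataFrame([
            dict(colony_id="C", queen_id=q, worker_group_id=w, apiary=1,
                 year=1, y_T1=y, y_T2=np.nan)]))
        system = assemble_mme(perf, ped, G, R)
        table, sol = solve_blup(system, method="splu")
        # single fixed-effect cell absorbs the record: everything shrinks to 0
        assert np.abs(sol[system.n_fixed:]).max() < 1e-12

    def test_row_order_permutation_invariance(self, rng):
        params = GeneticParams()
        G, R = build_G(params), params.residual_cov
        ped, perf, _ = small_population(rng)
        t1, _ = solve_blup(assemble_mme(perf, ped, G, R), method="splu")
        shuffled = PerformanceFile(
            perf.data.sample(frac=1.0, random_state=0).reset_index(drop=True))
        t2, _ = solve_blup(assemble_mme(shuffled, ped, G, R), method="splu")
        joined = t1.ebv.join(t2.ebv, lsuffix="_a", rsuffix="_b")
        for col in t1.ebv.columns:
            assert np.allclose(joined[f"{col}_a"], joined[f"{col}_b"],
                               atol=1e-9)

    def test_alt_style_missing_dams_get_late_ebvs_from_relatives(self, rng):
        """With no late record on any daughter, their late-trait EBVs are
        still non-trivial, driven by relatives' records and the
        between-trait correlation structure."""
        params = GeneticParams(r_T1T2=0.6)
        G, R = build_G(params), params.residual_cov
        ped, perf, entities = small_population(rng, missing_late=0.0)
        df = perf.data.copy()
        daughters = df.queen_id.str.startswith("K")
        df.loc[daughters, "y_T2"] = np.nan
        system = assemble_mme(perf := PerformanceFile(df), ped, G, R)
        table, _ = solve_blup(system, method="splu")
        k_ids = [q for (q, m, w) in entities if q.startswith("K")]
        late = table.ebv.loc[k_ids, ["W2", "Q2"]].to_numpy()
        assert np.isfinite(late).all()
        assert np.abs(late).max() > 0


class TestREML:
    def test_likelihood_matches_dense_restricted_likelihood(self, rng):
        params = GeneticParams()
        G, R = build_G(params), params.residual_cov
        ped, perf, _ = small_population(rng, n_dams=8, kids_per_dam=2,
                                        missing_late=0.0)
        ws = REMLWorkspace(perf, ped)
        st = compute_A(ped, include_worker_groups=False)
        system = assemble_mme(perf, ped, G, R)

        def dense_ll(Gm, Rm):
            n_nodes = len(st.ids)
            pos = {n: p for p, n in enumerate(st.ids)}
            Gt = np.kron(Gm, st.A)
            df = perf.data
            obs = [(r, t, df[f"y_T{t + 1}"].iloc[r]) for t in range(2)
                   for r in range(len(df))
                   if np.isfinite(df[f"y_T{t + 1}"].iloc[r])]
            obs.sort(key=lambda o: (o[1], o[0]))
            nob = len(obs)
            Z = np.zeros((nob, 4 * n_nodes))
            X = np.zeros((nob, len(system.fixed_labels)))
            fl = {lab: j for j, lab in enumerate(system.fixed_labels)}
            y = np.zeros(nob)
            Rv = np.zeros((nob, nob))
            for a, (r, t, v) in enumerate(obs):
                wi = ped.index_of(df["worker_group_id"].iloc[r])
                q, m = ped.dam[wi], ped.sire[wi]
                Z[a, 2 * t * n_nodes + pos[ped.ids[q]]] = 0.5
                Z[a, 2 * t * n_nodes + pos[ped.ids[m]]] = 1.0
                Z[a, (2 * t + 1) * n_nodes + pos[ped.ids[q]]] = 1.0
                X[a, fl[(df["apiary"].iloc[r], df["year"].iloc[r], t)]] = 1.0
                y[a] = v
            for a, (r1, t1, _) in enumerate(obs):
                for b, (r2, t2, _) in enumerate(obs):
                    if r1 == r2:
                        Rv[a, b] = Rm[t1, t2]
            V = Z @ Gt @ Z.T + Rv
            Vi = np.linalg.inv(V)
            XVX = X.T @ Vi @ X
            r = y - X @ np.linalg.solve(XVX, X.T @ Vi @ y)
            return -0.5 * (np.linalg.slogdet(V)[1]
                           + np.linalg.slogdet(XVX)[1] + r @ Vi @ y)

        for Gm, Rm in [(G, R), (0.7 * G, R), (G, 1.3 * R)]:
            assert -ws.neg_loglik(Gm, Rm) == pytest.approx(dense_ll(Gm, Rm),
                                                           abs=1e-8)

    def test_zero_genetic_variance_estimates_hit_boundary(self, rng):
        """Data with no genetic signal: genetic variances go to ~0."""
        ped, perf, _ = small_population(rng, n_dams=10, kids_per_dam=4,
                                        missing_late=1.0)
        df = perf.data.copy()
        df["y_T1"] = rng.normal(0, 1.0, len(df))  # pure noise
        perf = PerformanceFile(df)
        G0 = np.array([[0.5, 0.0], [0.0, 0.25]])
        est = reml_estimate(perf, ped, G0, np.array([[1.0]]), traits=(0,))
        assert est.converged
        assert np.diag(est.G).max() < 0.25
        assert est.R[0, 0] == pytest.approx(1.0, abs=0.35)


class TestSelectionIndex:
    def _table(self):
        ebv = pd.DataFrame(
            {"W1": [1.0, 0.0, 0.4], "Q1": [0.5, 0.2, 0.1],
             "W2": [0.0, 2.0, 0.3], "Q2": [0.0, 0.5, 0.2]},
            index=pd.Index(["a", "b", "c"], name="id"))
        wg = pd.DataFrame(
            {"W1": [0.2, 0.9, 0.1], "Q1": [0.1, 0.1, 0.0],
             "W2": [1.5, 0.0, 0.1], "Q2": [0.5, 0.0, 0.1]},
            index=pd.Index(["wa", "wb", "wc"], name="id"))
        table = EBVTable(ebv=pd.concat([ebv, wg]), traits=(0, 1),
                         wg_of_queen={"a": "wa", "b": "wb", "c": "wc"})
        return table

    def test_single_trait_weights_rank_on_that_trait_only(self):
        table = self._table()
        ranked = selection_index(table, (1.0, 0.0), "sire", ["a", "b", "c"])
        assert list(ranked.candidate) == ["a", "c", "b"]  # W1+Q1 sums

    def test_equal_weights_match_hand_computation(self):
        table = self._table()
        ranked = selection_index(table, (0.5, 0.5), "sire", ["a", "b", "c"])
        scores = dict(zip(ranked.candidate, ranked.score))
        assert scores["a"] == pytest.approx(0.5 * 1.5 + 0.5 * 0.0)
        assert scores["b"] == pytest.approx(0.5 * 0.2 + 0.5 * 2.5)
        assert scores["c"] == pytest.approx(0.5 * 0.5 + 0.5 * 0.5)

    def test_dam_role_uses_worker_group_ebvs(self):
        table = self._table()
        dam = selection_index(table, (0.5, 0.5), "dam", ["a", "b"])
        sire = selection_index(table, (0.5, 0.5), "sire", ["a", "b"])
        d = dict(zip(dam.candidate, dam.score))
        s = dict(zip(sire.candidate, sire.score))
        assert d["a"] == pytest.approx(0.5 * 0.3 + 0.5 * 2.0)
        assert d["a"] != pytest.approx(s["a"])

    def test_off_grid_weights_warn_but_run(self):
        with pytest.warns(UserWarning):
            selection_index(self._table(), (0.6, 0.4), "sire", ["a"])

    def test_ties_break_by_id(self):
        ebv = pd.DataFrame({"W1": [1.0, 1.0], "Q1": [0.0, 0.0],
                            "W2": [0.0, 0.0], "Q2": [0.0, 0.0]},
                           index=pd.Index(["z", "a"], name="id"))
        table = EBVTable(ebv=ebv, traits=(0, 1))
        ranked = selection_index(table, (1.0, 0.0), "sire", ["z", "a"])
        assert list(ranked.candidate) == ["a", "z"]


class TestIndexAccuracy:
    def test_perfect_and_anti_perfect(self):
        x = np.array([1.0, 2.0, 3.0])
        assert index_accuracy(x, x) == pytest.approx(1.0)
        assert index_accuracy(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_is_missing(self):
        with pytest.warns(UserWarning):
            out = index_accuracy(np.ones(5), np.arange(5.0))
        assert np.isnan(out)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            index_accuracy(np.ones(3), np.ones(4))
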