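"""Adjacency, TOM, soft-threshold selection, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cienet.network import (
    NetworkConfig,
    adjacency,
    connectivity_stats,
    detect_modules,
    module_eigengenes,
    pick_soft_threshold,
    scale_free_fit,
    topological_overlap,
)
from cienet.simulate import SimConfig, simulate_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the TOM definition."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def random_adjacency(n: int, rng) -> pd.DataFrame:
    a = rng.uniform(0, 1, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    ids = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=ids, columns=ids)


class TestAdjacency:
    def test_power_of_half_correlation(self, rng):
        t = np.linspace(0, 1, 40)
        x = np.vstack([t, 0.5 * t + np.sqrt(1 - 0.25) * rng.normal(size=40)])
        # force exact sample correlation 0.5 via Gram-Schmidt construction
        u = (x[0] - x[0].mean()) / np.linalg.norm(x[0] - x[0].mean())
        v = x[1] - x[1].mean()
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        y = 0.5 * u + np.sqrt(0.75) * v
        m = pd.DataFrame([u, y], index=["a", "b"])
        a = adjacency(m, NetworkConfig(power=6))
        assert a.loc["a", "b"] == pytest.approx(0.5**6, abs=1e-12)

    def test_power_one_is_absolute_correlation(self, small_sim):
        m = small_sim["expr"].iloc[:20]
        a = adjacency(m, NetworkConfig(power=1)).to_numpy()
        c = np.abs(np.corrcoef(m.to_numpy()))
        np.testing.assert_allclose(a, c, atol=1e-12)

    def test_perfectly_correlated_pair(self):
        x = np.linspace(0, 1, 10)
        m = pd.DataFrame([x, 2 * x + 1], index=["a", "b"])
        a = adjacency(m, NetworkConfig(power=7))
        assert a.loc["a", "b"] == pytest.approx(1.0)

    def test_signed_option(self, small_sim):
        m = small_sim["expr"].iloc[:15]
        a = adjacency(m, NetworkConfig(power=2, sign="signed")).to_numpy()
        c = np.corrcoef(m.to_numpy())
        np.fill_diagonal(c, 1.0)
        np.testing.assert_allclose(a, ((1 + c) / 2) ** 2, atol=1e-12)


class TestTOM:
    def test_two_gene_network_reduces_to_adjacency(self):
        for t in (0.2, 0.7, 0.95):
            a = pd.DataFrame([[1.0, t], [t, 1.0]], index=["a", "b"], columns=["a", "b"])
            tom = topological_overlap(a)
            assert tom.loc["a", "b"] == pytest.approx(t)

    def test_maximal_overlap_is_one(self):
        a = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        tom = topological_overlap(a)
        np.testing.assert_allclose(tom.to_numpy(), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            a = random_adjacency(15, rng)
            tom = topological_overlap(a).to_numpy()
            np.testing.assert_allclose(tom, brute_force_tom(a.to_numpy()), atol=1e-10)

    def test_bounds(self, small_tom):
        t = small_tom.to_numpy()
        assert t.min() >= 0.0 and t.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(t, t.T, atol=1e-12)


class TestSoftThreshold:
    def test_override_honored(self, small_sim):
        m = small_sim["expr"].iloc[:150]
        for beta in (6, 8):
            power, table = pick_soft_threshold(m, candidate_powers=[2, 4, 6, 8], override=beta)
            assert power == beta
            assert set(table.columns) == {"power", "signed_r2", "mean_k"}

    def test_power_law_degrees_fit_near_one(self, rng):
        # connectivity drawn from an exact discrete power law
        k = (rng.pareto(2.0, size=3000) + 1) * 2
        r2, mean_k = scale_free_fit(k)
        assert r2 > 0.9
        assert mean_k == pytest.approx(k.mean())

    def test_modular_data_reaches_threshold(self, small_sim):
        power, table = pick_soft_threshold(
            small_sim["expr"], candidate_powers=[1, 2, 4, 6, 9, 12], r2_threshold=0.8
        )
        chosen = table[table["power"] == power]["signed_r2"].iloc[0]
        passing = table[table["signed_r2"] >= 0.8]
        if len(passing):
            assert power == passing["power"].iloc[0]
        else:
            assert chosen == table["signed_r2"].max()


class TestDetectModules:
    def test_planted_blocks_recovered(self, small_sim, small_tom):
        cfg = NetworkConfig(power=6, deep_split=2, min_module_size=30)
        assign = detect_modules(small_tom, cfg)
        planted = pd.Series(small_sim["truth"].module_of_gene).loc[assign.index]
        coherent = planted.isin(["planted_1", "planted_3", "background"])
        ari = adjusted_rand_score(planted[coherent].to_numpy(), assign[coherent].to_numpy())
        assert ari >= 0.9

    def test_pure_noise_mostly_grey(self):
        cfg = SimConfig(
            n_genes=500, module_sizes=(3, 3), n_per_group=8, n_de_genes=0,
            trait_linked_modules={}, disrupted_modules={}, seed=21,
        )
        expr, _, _ = simulate_expression(cfg)
        ncfg = NetworkConfig(power=6, deep_split=2, min_module_size=30)
        tom = topological_overlap(adjacency(expr, ncfg))
        assign = detect_modules(tom, ncfg)
        assert (assign == "grey").mean() >= 0.9

    def test_deep_split_monotone_on_nested_blocks(self, rng):
        # two super-blocks, each made of two correlated sub-blocks
        n, per = 32, 50
        sup = rng.normal(size=(2, n))
        sub = rng.normal(size=(4, n))
        x = []
        for b in range(4):
            for _ in range(per):
                x.append(0.55 * sup[b // 2] + 0.55 * sub[b] + 0.35 * rng.normal(size=n))
        x = np.asarray(x)
        m = pd.DataFrame(x, index=[f"g{i}" for i in range(len(x))])
        counts = {}
        for ds in (0, 3):
            cfg = NetworkConfig(power=6, deep_split=ds, min_module_size=30)
            tom = topological_overlap(adjacency(m, cfg))
            assign = detect_modules(tom, cfg)
            counts[ds] = assign[assign != "grey"].nunique()
        assert counts[3] >= counts[0] >= 1

    def test_gene_order_invariance(self, small_sim):
        cfg = NetworkConfig(power=6, deep_split=2, min_module_size=30)
        expr = small_sim["expr"]
        tom = topological_overlap(adjacency(expr, cfg))
        a1 = detect_modules(tom, cfg)
        rng = np.random.default_rng(77)
        perm = rng.permutation(len(expr))
        tom_p = tom.iloc[perm, perm]
        a2 = detect_modules(tom_p, cfg).loc[a1.index]
        ari = adjusted_rand_score(a1.to_numpy(), a2.to_numpy())
        assert ari >= 0.95

    def test_labels_ordered_by_size(self, small_tom):
        cfg = NetworkConfig(power=6, deep_split=2, min_module_size=30)
        assign = detect_modules(small_tom, cfg)
        sizes = assign[assign != "grey"].value_counts()
        labels = list(sizes.index)
        expected_order = ["turquoise", "blue", "brown", "yellow"][: len(labels)]
        assert labels == expected_order
        assert (sizes.to_numpy()[:-1] >= sizes.to_numpy()[1:]).all()


class TestEigengenes:
    def test_identical_genes_module(self):
        x = np.sin(np.linspace(0, 3, 12))
        m = pd.DataFrame([x, x, x], index=["a", "b", "c"], columns=[f"s{i}" for i in range(12)])
        assign = pd.Series(["mod"] * 3, index=m.index)
        eig = module_eigengenes(m, assign)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(eig.loc["mod"].to_numpy(), z, atol=1e-8)

    def test_sign_flip_negates_eigengene(self, small_sim, planted_assignment):
        expr = small_sim["expr"].loc[planted_assignment.index]
        eig1 = module_eigengenes(expr, planted_assignment)
        eig2 = module_eigengenes(-expr, planted_assignment)
        for mod in eig1.index:
            np.testing.assert_allclose(
                eig2.loc[mod].to_numpy(), -eig1.loc[mod].to_numpy(), atol=1e-8
            )

    def test_zero_mean_across_samples(self, small_sim, planted_assignment):
        eig = module_eigengenes(small_sim["expr"].loc[planted_assignment.index], planted_assignment)
        np.testing.assert_allclose(eig.to_numpy().mean(axis=1), 0.0, atol=1e-10)

    def test_first_pc_optimality(self, small_sim, planted_assignment):
        """The eigengene explains at least as much standardized variance as
        any single member gene's profile would."""
        expr = small_sim["expr"].loc[planted_assignment.index]
        eig = module_eigengenes(expr, planted_assignment)
        mod = "planted_1"
        genes = planted_assignment.index[planted_assignment == mod]
        z = expr.loc[genes].to_numpy()
        z = (z - z.mean(1, keepdims=True)) / z.std(1, keepdims=True)
        e = eig.loc[mod].to_numpy()

        def explained(v):
            v = (v - v.mean()) / np.linalg.norm(v - v.mean())
            return ((z @ v) ** 2).sum()

        best_gene = max(explained(z[i]) for i in range(len(genes)))
        assert explained(e) >= best_gene - 1e-8

    def test_member_kme_exceeds_nonmember(self, small_sim, planted_assignment):
        expr = small_sim["expr"]
        cfg = NetworkConfig(power=6)
        adj = adjacency(expr.loc[planted_assignment.index], cfg)
        eig = module_eigengenes(expr.loc[planted_assignment.index], planted_assignment)
        conn = connectivity_stats(adj, planted_assignment, eig, expr.loc[planted_assignment.index])
        mod = "planted_1"
        e = eig.loc[mod].to_numpy()
        members = conn[conn["module"] == mod]["kME"].to_numpy()
        others = expr.loc[planted_assignment.index[planted_assignment == "planted_3"]].to_numpy()
        oc = np.array(
            [abs(np.corrcoef(o, e)[0, 1]) for o in others]
        )
        wins = np.mean(members[:, None] > oc[None, :])
        assert wins >= 0.95

    def test_connectivity_invariants(self, small_sim, planted_assignment):
        cfg = NetworkConfig(power=6)
        expr = small_sim["expr"].loc[planted_assignment.index]
        adj = adjacency(expr, cfg)
        eig = module_eigengenes(expr, planted_assignment)
        conn = connectivity_stats(adj, planted_assignment, eig, expr)
        assert (conn["kIM"] <= conn["kTotal"] + 1e-9).all()
        assert conn["kME"].abs().max() <= 1.0 + 1e-12
        assert (conn["kIM"] >= 0).all()
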