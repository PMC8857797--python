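"""Soft threshold, TOM, module detection, eigengenes, traits, hubs."""

import numpy as np
import pandas as pd
import pytest

from cerna_seeker import wgcna
from cerna_seeker.simulate import simulate_coexpression_matrix


def brute_force_tom(a):
    n = a.shape[0]
    t = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            t[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return t


def random_adjacency(n, seed):
    rng = np.random.default_rng(seed)
    c = rng.uniform(0, 1, (n, n))
    a = (c + c.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestTOM:
    def test_two_gene_hand_value(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        tom = wgcna.tom_similarity(a)
        assert tom[0, 1] == pytest.approx(0.5)

    def test_identity_adjacency(self):
        assert np.allclose(wgcna.tom_similarity(np.eye(5)), np.eye(5))

    def test_all_ones_adjacency(self):
        tom = wgcna.tom_similarity(np.ones((4, 4)))
        assert np.allclose(tom, 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        a = random_adjacency(20, seed)
        assert np.abs(wgcna.tom_similarity(a) - brute_force_tom(a)).max() < 1e-10

    def test_symmetry_bounds_and_diagonal(self):
        tom = wgcna.tom_similarity(random_adjacency(15, 99))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            wgcna.tom_similarity(np.array([[1.0, 0.2], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            wgcna.tom_similarity(np.array([[1.0, 1.5], [1.5, 1.0]]))


class TestSoftThreshold:
    def test_connectivity_decreases_with_power(self):
        expr, _ = simulate_coexpression_matrix(3, 30, 50, 0.6, seed=1)
        scan = wgcna.pick_soft_threshold(expr, powers=[1, 6])
        k = scan.table.set_index("power")["mean_connectivity"]
        assert k[1] > k[6]

    def test_module_structure_reaches_scale_free_fit(self):
        expr, _ = simulate_coexpression_matrix(3, 50, 50, 0.7, seed=0)
        scan = wgcna.pick_soft_threshold(expr)
        assert scan.table["signed_r2"].max() >= 0.8

    def test_perfectly_correlated_pair_has_unit_adjacency(self):
        x = np.linspace(0, 1, 20)
        expr = pd.DataFrame({"g1": x, "g2": 2 * x + 3})
        for power in (1, 4, 9):
            adj = wgcna.adjacency_matrix(expr, power)
            assert adj[0, 1] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            wgcna.pick_soft_threshold(expr)


class TestModules:
    def _fit(self, expr, min_size=30):
        scan = wgcna.pick_soft_threshold(expr)
        adj = wgcna.adjacency_matrix(expr, scan.recommended_power)
        tom = wgcna.tom_similarity(adj)
        return wgcna.cluster_modules(1 - tom, list(expr.columns),
                                     min_size=min_size, expr=expr)

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score
        expr, labels = simulate_coexpression_matrix(3, 50, 50, 0.7, seed=0)
        assign = self._fit(expr)
        ari = adjusted_rand_score(labels.values,
                                  assign.labels.loc[labels.index].values)
        assert ari >= 0.8
        assert len(assign.module_sizes()) == 3

    def test_min_size_larger_than_gene_count_gives_grey(self):
        expr, _ = simulate_coexpression_matrix(2, 20, 30, 0.7, seed=2)
        assign = self._fit(expr, min_size=100)
        assert (assign.labels == 0).all()

    def test_gene_permutation_invariance(self):
        from sklearn.metrics import adjusted_rand_score
        expr, _ = simulate_coexpression_matrix(3, 40, 40, 0.7, seed=3)
        assign1 = self._fit(expr)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.columns)
        assign2 = self._fit(expr[perm])
        joined = pd.concat([assign1.labels.rename("a"),
                            assign2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_duplicated_module_collapses(self):
        rng = np.random.default_rng(4)
        f = rng.standard_normal(40)
        cols = {f"g{i}": 0.9 * f + 0.1 * rng.standard_normal(40)
                for i in range(20)}
        expr = pd.DataFrame(cols)
        assign = self._fit(expr, min_size=5)
        assert len(assign.module_sizes()) == 1


class TestEigengenes:
    def test_identical_genes_explain_everything(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        expr = pd.DataFrame({f"g{i}": x for i in range(6)})
        labels = pd.Series(1, index=expr.columns)
        me = wgcna.module_eigengenes(expr, labels)
        assert me.variance_explained["ME1"] == pytest.approx(1.0)
        z = (x - x.mean()) / x.std()
        cor = np.corrcoef(me.values["ME1"], z)[0, 1]
        assert cor == pytest.approx(1.0)

    def test_two_gene_variance_explained(self):
        # correlation 0.8 -> eigenvalues (1.8, 0.2) -> share 0.9
        rng = np.random.default_rng(6)
        n = 200_000
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        expr = pd.DataFrame({"g1": a, "g2": b})
        me = wgcna.module_eigengenes(expr, pd.Series(1, index=expr.columns))
        assert me.variance_explained["ME1"] == pytest.approx(0.9, abs=0.01)

    def test_sign_orientation_is_flip_consistent(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.standard_normal((30, 8)),
                            columns=[f"g{i}" for i in range(8)])
        labels = pd.Series(1, index=expr.columns)
        me1 = wgcna.module_eigengenes(expr, labels)
        me2 = wgcna.module_eigengenes(-expr, labels)
        assert np.allclose(me1.values["ME1"], -me2.values["ME1"])

    def test_singleton_module(self):
        rng = np.random.default_rng(8)
        expr = pd.DataFrame({"g1": rng.standard_normal(20)})
        me = wgcna.module_eigengenes(expr, pd.Series(1, index=expr.columns))
        z = (expr["g1"] - expr["g1"].mean()) / expr["g1"].std()
        cor = np.corrcoef(me.values["ME1"], z)[0, 1]
        assert cor == pytest.approx(1.0)


class TestMerging:
    def _assign(self, labels, expr):
        return wgcna.ModuleAssignment(labels=labels,
                                      merge_heights=np.array([]),
                                      min_size=1, cut_height=0.0)

    def test_highly_correlated_modules_merge(self):
        rng = np.random.default_rng(9)
        f = rng.standard_normal(50)
        cols = {}
        labels = {}
        for m, shift in ((1, 0.0), (2, 0.0)):  # same driver -> ME cor ~ 1
            for i in range(5):
                g = f"m{m}g{i}"
                cols[g] = f + rng.normal(0, 0.3, 50) + shift
                labels[g] = m
        # a third module from an independent factor stays separate
        f2 = rng.standard_normal(50)
        for i in range(5):
            g = f"m3g{i}"
            cols[g] = f2 + rng.normal(0, 0.3, 50)
            labels[g] = 3
        expr = pd.DataFrame(cols)
        labels = pd.Series(labels)
        merged, me = wgcna.merge_close_modules(expr, self._assign(labels, expr))
        assert merged.labels.max() == 2
        # the two same-driver modules carry one label
        a = merged.labels["m1g0"]
        assert all(merged.labels[f"m1g{i}"] == a for i in range(5))
        assert all(merged.labels[f"m2g{i}"] == a for i in range(5))

    def test_distant_modules_untouched_and_idempotent(self):
        rng = np.random.default_rng(10)
        cols, labels = {}, {}
        for m in (1, 2, 3):
            f = rng.standard_normal(60)
            for i in range(4):
                g = f"m{m}g{i}"
                cols[g] = f + rng.normal(0, 0.2, 60)
                labels[g] = m
        expr = pd.DataFrame(cols)
        labels = pd.Series(labels)
        once, _ = wgcna.merge_close_modules(expr, self._assign(labels, expr))
        twice, _ = wgcna.merge_close_modules(expr, once)
        assert once.labels.max() == 3
        pd.testing.assert_series_equal(once.labels, twice.labels)


class TestTraitsAndHubs:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(11)
        f = rng.standard_normal(40)
        expr = pd.DataFrame({f"g{i}": f + rng.normal(0, 0.2, 40)
                             for i in range(10)})
        labels = pd.Series(1, index=expr.columns)
        me = wgcna.module_eigengenes(expr, labels)
        traits = pd.DataFrame({"t": me.values["ME1"]}, index=expr.index)
        r_tab, p_tab = wgcna.module_trait_correlation(me, traits)
        assert r_tab.loc["ME1", "t"] == pytest.approx(1.0)
        assert p_tab.loc["ME1", "t"] < 1e-10

    def test_planted_trait_module_attains_max_correlation(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            expr, labels = simulate_coexpression_matrix(4, 25, 50, 0.7,
                                                        seed=2000 + seed)
            me = wgcna.module_eigengenes(expr, labels)
            driver = me.values["ME1"].to_numpy()
            driver = (driver - driver.mean()) / driver.std()
            trait = driver + rng.normal(0, 0.5, 50)
            traits = pd.DataFrame({"t": trait}, index=expr.index)
            r_tab, _ = wgcna.module_trait_correlation(me, traits)
            hits += r_tab["t"].abs().idxmax() == "ME1"
        assert hits >= 18

    def test_constant_trait_warns_and_is_missing(self):
        rng = np.random.default_rng(12)
        expr = pd.DataFrame({f"g{i}": rng.standard_normal(30)
                             for i in range(5)})
        me = wgcna.module_eigengenes(expr, pd.Series(1, index=expr.columns))
        traits = pd.DataFrame({"t": np.ones(30)}, index=expr.index)
        with pytest.warns(UserWarning):
            r_tab, _ = wgcna.module_trait_correlation(me, traits)
        assert np.isnan(r_tab.loc["ME1", "t"])

    def test_hub_perfect_gene_passes_and_strict_cut(self):
        rng = np.random.default_rng(13)
        f = rng.standard_normal(40)
        expr = pd.DataFrame({f"g{i}": f + rng.normal(0, 0.1, 40)
                             for i in range(8)})
        labels = pd.Series(1, index=expr.columns)
        me = wgcna.module_eigengenes(expr, labels)
        trait = pd.Series(me.values["ME1"].to_numpy(), index=expr.index)
        tab = wgcna.hub_genes(expr, me, trait, labels, 1)
        assert tab["passing"].all()
        none = wgcna.hub_genes(expr, me, trait, labels, 1, mm_cut=1.0)
        assert not none["passing"].any()

    def test_hub_selection_monotone_in_cuts(self):
        rng = np.random.default_rng(14)
        f = rng.standard_normal(60)
        expr = pd.DataFrame({f"g{i}": f + rng.normal(0, 0.5 + 0.1 * i, 60)
                             for i in range(12)})
        labels = pd.Series(1, index=expr.columns)
        me = wgcna.module_eigengenes(expr, labels)
        trait = pd.Series(f + rng.normal(0, 0.8, 60), index=expr.index)
        tight = wgcna.hub_genes(expr, me, trait, labels, 1,
                                mm_cut=0.8, gs_cut=0.4)
        loose = wgcna.hub_genes(expr, me, trait, labels, 1,
                                mm_cut=0.6, gs_cut=0.2)
        assert set(tight[tight["passing"]]["gene"]) <= \
            set(loose[loose["passing"]]["gene"])

    def test_planted_hub_genes_pass_default_cuts(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            latent = rng.standard_normal(60)
            cols = {f"hub{i}": 0.95 * latent
                    + np.sqrt(1 - 0.95**2) * rng.standard_normal(60)
                    for i in range(5)}
            cols.update({f"bg{i}": 0.6 * latent
                         + 0.8 * rng.standard_normal(60) for i in range(10)})
            expr = pd.DataFrame(cols)
            labels = pd.Series(1, index=expr.columns)
            me = wgcna.module_eigengenes(expr, labels)
            trait = pd.Series(latent + rng.normal(0, 0.5, 60),
                              index=expr.index)
            tab = wgcna.hub_genes(expr, me, trait, labels, 1).set_index("gene")
            hits += all(tab.loc[f"hub{i}", "passing"] for i in range(5))
        assert hits >= 18
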