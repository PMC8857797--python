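"""Hypergeometric shared-miRNA test, pair correlation, triplet calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cerna_seeker import cerna, diffexpr
from cerna_seeker.targets import BipartiteTargeting


def enumerate_upper_tail(N, K, n, k):
    """P(X >= k) by enumerating all C(N, n) draws from a universe of N
    elements whose first K form the lncRNA target set."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestSharedMirnaTest:
    def test_hand_worked_example(self):
        # N=10, K=4, n=5, k=4: C(4,4)*C(6,1)/C(10,5) = 6/252
        universe = {f"m{i}" for i in range(10)}
        lnc = {f"m{i}" for i in range(4)}
        mrna = {f"m{i}" for i in range(4)} | {"m9"}
        k, p = cerna.shared_mirna_test(lnc, mrna, universe)
        assert k == 4
        assert p == pytest.approx(6 / 252, rel=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = {f"m{i}" for i in range(6)}
        k, p = cerna.shared_mirna_test({"m0"}, {"m5"}, universe)
        assert (k, p) == (0, 1.0)

    def test_degenerate_full_sets(self):
        universe = {f"m{i}" for i in range(7)}
        k, p = cerna.shared_mirna_test(universe, universe, universe)
        assert k == 7
        assert p == pytest.approx(1.0)

    def test_requires_containment(self):
        with pytest.raises(ValueError):
            cerna.shared_mirna_test({"x"}, {"m0"}, {"m0"})

    def test_matches_enumeration_small_universes(self):
        for N in (4, 6, 8):
            universe = {f"m{i}" for i in range(N)}
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    lnc = {f"m{i}" for i in range(K)}
                    # overlap forced to k by picking n members accordingly
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        mrna = ({f"m{i}" for i in range(k)}
                                | {f"m{K + i}" for i in range(n - k)})
                        got_k, got_p = cerna.shared_mirna_test(lnc, mrna,
                                                               universe)
                        assert got_k == k
                        if k > 0:
                            want = enumerate_upper_tail(N, K, n, k)
                            assert got_p == pytest.approx(want, rel=1e-12)

    def test_monotone_nonincreasing_in_k(self):
        N, K, n = 20, 8, 10
        universe = {f"m{i}" for i in range(N)}
        lnc = {f"m{i}" for i in range(K)}
        last = 1.1
        for k in range(max(0, K + n - N), min(K, n) + 1):
            mrna = ({f"m{i}" for i in range(k)}
                    | {f"m{K + i}" for i in range(n - k)})
            _, p = cerna.shared_mirna_test(lnc, mrna, universe)
            assert p <= last + 1e-15
            last = p


class TestPairCorrelation:
    def test_perfect_linear_dependence(self):
        x = np.arange(10.0)
        r, p = cerna.pair_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_half_correlation_p_value(self):
        # r = 0.5 at m = 20 -> t = 2.4495 with 18 df; two-sided p by
        # independent numeric integration of the t density
        rng = np.random.default_rng(0)
        m = 20
        for _ in range(50):  # random vectors rotated to exact r = 0.5
            a = rng.standard_normal(m)
            b = rng.standard_normal(m)
            a = (a - a.mean()) / a.std()
            b = b - b.mean()
            b -= a * (a @ b) / (a @ a)
            b /= np.sqrt((b @ b) / m)
            y = 0.5 * a + np.sqrt(1 - 0.25) * b
            r, p = cerna.pair_correlation(a, y)
            if abs(r - 0.5) < 1e-10:
                break
        df = m - 2
        t_obs = 0.5 * np.sqrt(df / (1 - 0.25))
        const = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi)
                                            * math.gamma(df / 2))
        grid = np.linspace(t_obs, 60, 400_000)
        dens = const * (1 + grid**2 / df) ** (-(df + 1) / 2)
        p_oracle = 2 * np.trapezoid(dens, grid)
        assert p_oracle == pytest.approx(0.0248, abs=2e-4)
        assert p == pytest.approx(p_oracle, rel=1e-4)

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        hits = 0
        reps = 1000
        for _ in range(reps):
            _, p = cerna.pair_correlation(rng.standard_normal(20),
                                          rng.standard_normal(20))
            hits += p < 0.05
        assert 0.03 <= hits / reps <= 0.07

    def test_zero_variance_returns_null(self):
        r, p = cerna.pair_correlation(np.ones(10), np.arange(10.0))
        assert (r, p) == (0.0, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cerna.pair_correlation(np.ones(5), np.ones(6))


def _expr(rows: dict, samples=8, rng=None) -> pd.DataFrame:
    return pd.DataFrame(rows, index=[f"s{i}" for i in range(samples)]).T


class TestNetwork:
    def _one_pair_targeting(self):
        return BipartiteTargeting(
            mirna_universe={f"m{i}" for i in range(1, 13)},
            lnc_targets={"L1": {"m1", "m2", "m3"}},
            mrna_targets={"G1": {"m1", "m2", "m3"}},
        )

    def test_negative_correlation_rejected(self):
        x = np.arange(8.0)
        expr_l = _expr({"L1": x})
        expr_m = _expr({"G1": -x})
        net = cerna.build_cerna_network(self._one_pair_targeting(),
                                        expr_l, expr_m)
        row = net.pairs.iloc[0]
        assert row["hyper_p"] < 0.05
        assert row["pearson_r"] < -0.9
        assert not row["accepted"]
        assert net.triplets.empty

    def test_positive_pair_expands_to_triplets(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(8)
        expr_l = _expr({"L1": x})
        expr_m = _expr({"G1": x + rng.normal(0, 0.05, 8)})
        net = cerna.build_cerna_network(self._one_pair_targeting(),
                                        expr_l, expr_m)
        assert net.pairs.iloc[0]["accepted"]
        assert len(net.triplets) == 3  # one per shared miRNA
        assert set(net.triplets["mirna_id"]) == {"m1", "m2", "m3"}

    def test_no_shared_mirna_never_scored(self):
        bp = BipartiteTargeting(mirna_universe={"m1", "m2"},
                                lnc_targets={"L1": {"m1"}},
                                mrna_targets={"G1": {"m2"}})
        x = np.arange(8.0)
        net = cerna.build_cerna_network(bp, _expr({"L1": x}),
                                        _expr({"G1": x}))
        assert net.pairs.empty

    def test_threshold_monotonicity(self, default_dataset, default_bipartite):
        tumor = default_dataset.tumor_samples()
        lnc = diffexpr.log_cpm(default_dataset.counts["lncrna"])[tumor]
        mrna = diffexpr.log_cpm(default_dataset.counts["mrna"])[tumor]
        strict = cerna.build_cerna_network(default_bipartite, lnc, mrna,
                                           r_cut=0.5, p_cut=0.05)
        loose = cerna.build_cerna_network(default_bipartite, lnc, mrna,
                                          r_cut=0.3, p_cut=0.2)
        acc_strict = set(zip(strict.accepted_pairs()["lncrna_id"],
                             strict.accepted_pairs()["mrna_id"]))
        acc_loose = set(zip(loose.accepted_pairs()["lncrna_id"],
                            loose.accepted_pairs()["mrna_id"]))
        assert acc_strict <= acc_loose


class TestSubnetworkAndExport:
    def _toy_net(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10)
        bp = BipartiteTargeting(
            mirna_universe={f"m{i}" for i in range(10)},
            lnc_targets={"L1": {"m0", "m1", "m2"}, "L2": {"m3", "m4", "m5"}},
            mrna_targets={"G1": {"m0", "m1", "m2"}, "G2": {"m3", "m4", "m5"}},
        )
        expr_l = pd.DataFrame([x, x + rng.normal(0, 0.05, 10)],
                              index=["L1", "L2"])
        expr_m = pd.DataFrame([x + rng.normal(0, 0.05, 10),
                               x + rng.normal(0, 0.05, 10)],
                              index=["G1", "G2"])
        return cerna.build_cerna_network(bp, expr_l, expr_m)

    def test_identity_and_empty_extraction(self):
        net = self._toy_net()
        all_lncs = set(net.triplets["lncrna_id"])
        same = cerna.extract_subnetwork(net, all_lncs)
        pd.testing.assert_frame_equal(same.triplets, net.triplets)
        empty = cerna.extract_subnetwork(net, set())
        assert empty.triplets.empty and empty.graph.number_of_nodes() == 0

    def test_single_lncrna_relation_count(self):
        net = self._toy_net()
        sub = cerna.extract_subnetwork(net, {"L1"})
        assert cerna.relations_per_lncrna(sub).to_dict() == {"L1": 3}

    def test_one_triplet_network_edge_rows(self, tmp_path):
        bp = BipartiteTargeting(mirna_universe={f"m{i}" for i in range(9)},
                                lnc_targets={"L1": {"m0", "m1", "m2"}},
                                mrna_targets={"G1": {"m0", "m3", "m4"}})
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        net = cerna.build_cerna_network(
            bp, pd.DataFrame([x], index=["L1"]),
            pd.DataFrame([x + rng.normal(0, 0.05, 10)], index=["G1"]),
            hyper_cut=1.1)  # the pair shares one miRNA; accept on correlation
        assert len(net.triplets) == 1
        _, edge_path = cerna.export_network(net, tmp_path)
        edges = pd.read_csv(edge_path, sep="\t")
        assert len(edges) == 3
        assert set(edges["edge_type"]) == {"lncRNA-miRNA", "miRNA-mRNA",
                                           "lncRNA-mRNA"}

    def test_empty_network_export_headers_only(self, tmp_path):
        net = cerna.CeRNANetwork()
        node_path, edge_path = cerna.export_network(net, tmp_path)
        assert pd.read_csv(node_path, sep="\t").empty
        assert pd.read_csv(edge_path, sep="\t").empty

    def test_export_is_deterministic(self, tmp_path):
        net = self._toy_net()
        p1 = cerna.export_network(net, tmp_path / "a")
        p2 = cerna.export_network(net, tmp_path / "b")
        for a, b in zip(p1, p2):
            assert a.read_bytes() == b.read_bytes()
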