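"""Synergy-network rules, integrated assembly, hubs and edge overlap."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirnca import (
    ConnectivityPattern,
    build_integrated_network,
    build_synergy_network,
    edge_overlap,
    hub_ranking,
    pairwise_activity_correlation,
    shared_target_counts,
)


def pattern(support, regs=None, tgs=None):
    support = np.asarray(support, dtype=np.int8)
    n, l = support.shape
    regs = regs or [f"r{j}" for j in range(l)]
    tgs = tgs or [f"t{i}" for i in range(n)]
    return ConnectivityPattern(regs, tgs, support)


class TestActivityCorrelation:
    def test_identical_and_negated_rows(self):
        x = np.array([[1.0, 2.0, 3.0, 1.0]])
        T = np.vstack([x, x, -x])
        corr = pairwise_activity_correlation(T)
        assert corr.iat[0, 1] == pytest.approx(1.0)
        assert corr.iat[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(corr), 1.0)

    def test_cos_sin_orthogonal_over_full_period(self):
        t = np.arange(16) / 16.0  # one full period, end point not duplicated
        T = np.vstack([np.cos(2 * np.pi * t), np.sin(2 * np.pi * t)])
        corr = pairwise_activity_correlation(T)
        assert abs(corr.iat[0, 1]) < 1e-10

    def test_constant_row_recorded_as_zero_with_flag(self):
        T = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "b"]
        )
        corr = pairwise_activity_correlation(T)
        assert corr.loc["a", "b"] == 0.0
        assert corr.attrs["constant_rows"] == ["b"]

    def test_too_few_timepoints_refused(self):
        with pytest.raises(ValueError):
            pairwise_activity_correlation(np.ones((2, 2)))


class TestSharedTargets:
    def test_enumerated_cases(self):
        # r0 targets {t0,t1,t2}, r1 targets {t1,t2,t3}, r2 disjoint {t4}
        sup = np.array(
            [[1, 0, 0], [1, 1, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1]]
        )
        counts = shared_target_counts(pattern(sup))
        assert counts.loc["r0", "r1"] == 2
        assert counts.loc["r0", "r2"] == 0
        assert counts.loc["r0", "r0"] == 3  # diagonal = out-degree

    def test_identical_sets(self):
        sup = np.ones((5, 2), dtype=np.int8)
        counts = shared_target_counts(pattern(sup))
        assert counts.iat[0, 1] == 5


class TestSynergyNetwork:
    def make(self, pcc, shared_n):
        """Two regulators with controllable pcc and shared-target count."""
        M = 12
        t = np.linspace(0, 1, M)
        a = np.sin(2 * np.pi * t)
        rng = np.random.default_rng(0)
        # rotate a noise direction to hit the requested correlation
        noise = rng.standard_normal(M)
        noise -= noise.mean()
        a0 = a - a.mean()
        noise -= a0 * (noise @ a0) / (a0 @ a0)
        b = pcc * a0 / np.linalg.norm(a0) + np.sqrt(1 - pcc**2) * noise / np.linalg.norm(noise)
        T = np.vstack([a, b])
        n_only = 2
        N = shared_n + 2 * n_only
        sup = np.zeros((N, 2), dtype=np.int8)
        sup[:shared_n, :] = 1
        sup[shared_n : shared_n + n_only, 0] = 1
        sup[shared_n + n_only :, 1] = 1
        Z0 = pattern(sup, regs=["rA", "rB"])
        return T, Z0

    def test_edge_present_above_both_thresholds(self):
        T, Z0 = self.make(pcc=0.95, shared_n=5)
        g = build_synergy_network(T, Z0)
        assert g.has_edge("rA", "rB")
        data = g.get_edge_data("rA", "rB")
        assert data["shared"] == 5
        assert data["pcc"] == pytest.approx(0.95, abs=1e-9)

    def test_correlation_boundary_is_strict(self):
        T, Z0 = self.make(pcc=0.7, shared_n=10)
        g = build_synergy_network(T, Z0)  # pcc == 0.7 not > 0.7
        assert not g.has_edge("rA", "rB")
        T, Z0 = self.make(pcc=0.69, shared_n=10)
        assert not build_synergy_network(T, Z0).has_edge("rA", "rB")

    def test_shared_boundary_inclusive(self):
        T, Z0 = self.make(pcc=0.9, shared_n=2)
        assert not build_synergy_network(T, Z0).has_edge("rA", "rB")
        T, Z0 = self.make(pcc=0.9, shared_n=3)
        assert build_synergy_network(T, Z0).has_edge("rA", "rB")

    def test_id_mismatch_reported(self):
        T, Z0 = self.make(pcc=0.9, shared_n=3)
        Tdf = pd.DataFrame(T, index=["rA", "WRONG"])
        with pytest.raises(ValueError, match="rB"):
            build_synergy_network(Tdf, Z0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        truthT = rng.standard_normal((6, 10))
        sup = (rng.random((30, 6)) < 0.4).astype(np.int8)
        sup[sup.sum(axis=1) == 0, 0] = 1
        Z0 = pattern(sup)
        Tdf = pd.DataFrame(truthT, index=Z0.regulators)
        g1 = build_synergy_network(Tdf, Z0, pcc_threshold=0.2, min_shared=2)
        perm = rng.permutation(6)
        g2 = build_synergy_network(Tdf.iloc[perm], Z0, pcc_threshold=0.2, min_shared=2)
        assert set(map(frozenset, g1.edges())) == set(map(frozenset, g2.edges()))

    def test_edge_attributes_revalidate(self):
        rng = np.random.default_rng(6)
        T = rng.standard_normal((6, 10))
        sup = (rng.random((30, 6)) < 0.4).astype(np.int8)
        sup[sup.sum(axis=1) == 0, 0] = 1
        Z0 = pattern(sup)
        g = build_synergy_network(T, Z0, pcc_threshold=0.2, min_shared=1)
        corr = pairwise_activity_correlation(pd.DataFrame(T, index=Z0.regulators))
        shared = shared_target_counts(Z0)
        assert g.number_of_edges() > 0
        for u, v, data in g.edges(data=True):
            assert data["pcc"] == pytest.approx(corr.loc[u, v])
            assert data["shared"] == shared.loc[u, v]


class TestIntegratedNetwork:
    def test_empty_tables_empty_network(self):
        net = build_integrated_network()
        assert net.graph.number_of_nodes() == 0
        assert net.number_of_edges() == 0

    def test_enumerated_assembly_with_roles(self):
        net = build_integrated_network(
            mirna_tg=[("m1", "g1"), ("m2", "g2")],
            tf_tg=[("f1", "g1"), ("f2", "g2")],
            tf_mirna=[("f1", "m1")],
        )
        assert net.number_of_edges() == 5
        assert net.roles["m1"] == {"miRNA"}
        assert net.roles["f1"] == {"TF"}
        assert net.roles["g1"] == {"TG"}

    def test_duplicate_edges_collapse(self):
        net = build_integrated_network(
            tf_tg=[("f1", "g1"), ("f1", "g1"), ("f1", "g1")]
        )
        assert net.number_of_edges() == 1

    def test_entity_can_hold_multiple_roles(self):
        net = build_integrated_network(
            tf_tg=[("f1", "f2"), ("f2", "g1")]
        )
        assert net.roles["f2"] == {"TF", "TG"}

    def test_node_filter_restricts_target_genes(self):
        net = build_integrated_network(
            mirna_tg=[("m1", "g1"), ("m1", "g2")],
            tf_mirna=[("f1", "m1")],
            node_filter={"g1"},
        )
        assert "g2" not in net.graph
        assert net.graph.has_edge("f1", "m1")

    def test_degree_sums_balance(self):
        rng = np.random.default_rng(7)
        mirna_tg = [(f"m{rng.integers(5)}", f"g{rng.integers(20)}") for _ in range(40)]
        tf_tg = [(f"f{rng.integers(4)}", f"g{rng.integers(20)}") for _ in range(30)]
        net = build_integrated_network(mirna_tg=mirna_tg, tf_tg=tf_tg)
        g = net.graph
        assert sum(d for _, d in g.in_degree()) == sum(d for _, d in g.out_degree())
        assert sum(d for _, d in g.in_degree()) == net.directed_edge_count()

    def test_malformed_rows_skipped_and_counted(self):
        net = build_integrated_network(mirna_tg=[("m1", "g1"), ("m2",), ("", "g3")])
        assert net.number_of_edges() == 1
        assert net.n_skipped == 2


class TestHubRanking:
    def test_star_center_first(self):
        net = build_integrated_network(
            tf_tg=[("hub", f"g{i}") for i in range(6)]
        )
        ranking = hub_ranking(net, role="TF")
        assert ranking[0] == ("hub", 6)

    def test_tie_broken_lexicographically(self):
        net = build_integrated_network(
            tf_tg=[("b", "g1"), ("a", "g2")]
        )
        assert hub_ranking(net, role="TF") == [("a", 1), ("b", 1)]

    def test_planted_hub_recovered(self):
        rng = np.random.default_rng(8)
        edges = [("HUB", f"g{i}") for i in range(30)]
        for j in range(10):
            picks = rng.choice(200, size=5, replace=False)
            edges += [(f"m{j}", f"g{p}") for p in picks]
        net = build_integrated_network(mirna_tg=edges)
        ranking = hub_ranking(net, role="miRNA", top_k=5)
        assert ranking[0][0] == "HUB" and ranking[0][1] == 30

    def test_synergy_incidence_counts_once_per_endpoint(self):
        syn = nx.Graph()
        syn.add_edge("m1", "m2", pcc=0.9, shared=4)
        net = build_integrated_network(
            mirna_tg=[("m1", "g1")], synergy=syn
        )
        assert net.total_degree("m1") == 2  # one TG edge + one synergy incidence
        assert net.total_degree("m2") == 1


class TestEdgeOverlap:
    def test_identical_and_disjoint(self):
        a = nx.Graph([("x", "y"), ("y", "z")])
        assert edge_overlap(a, [("y", "x"), ("z", "y")]) == (2, 1.0)
        assert edge_overlap(a, [("p", "q")]) == (0, 0.0)

    def test_reported_study_overlap_fraction(self):
        """258 shared out of 314 predicted pairs is > 80% overlap."""
        a = nx.Graph()
        for i in range(314):
            a.add_edge(f"m{i}", f"m{i + 400}")
        external = [(f"m{i}", f"m{i + 400}") for i in range(258)]
        external += [(f"q{i}", f"q{i + 1000}") for i in range(100)]
        count, frac = edge_overlap(a, external)
        assert count == 258
        assert frac == pytest.approx(258 / 314)
        assert frac > 0.80
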