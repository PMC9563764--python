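import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctpathway.gpcm import PathwaySet
from ctpathway.redundancy import (
    SimilarityNetwork,
    build_similarity_network,
    jaccard,
    mcl_cluster,
    select_display,
)
from ctpathway.significance import EnrichmentResult


def pset(pid, genes):
    return PathwaySet(id=pid, name=pid, genes=frozenset(genes))


def result(pid, fdr, ps=1.0):
    return EnrichmentResult(
        pathway_id=pid, name=pid, source_db="", n=3, ps=ps,
        p_empirical=fdr, p_final=fdr, fdr=fdr, significant=True,
    )


class TestJaccard:
    def test_identical(self):
        assert jaccard({"A", "B"}, {"A", "B"}) == 1.0

    def test_disjoint(self):
        assert jaccard({"A"}, {"B"}) == 0.0

    def test_half(self):
        assert jaccard({"A", "B", "C"}, {"B", "C", "D"}) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            jaccard(set(), {"A"})


class TestSimilarityNetwork:
    def test_cutoff_one_links_only_identical(self):
        sets = [pset("P1", "ABC"), pset("P2", "ABC"), pset("P3", "ABD")]
        net = build_similarity_network(sets, cutoff=1.0)
        assert [(a, b) for a, b, _ in net.edges] == [("P1", "P2")]

    def test_cutoff_zero_links_all_pairs(self):
        sets = [pset("P1", "AB"), pset("P2", "CD")]
        net = build_similarity_network(sets, cutoff=0.0)
        assert len(net.edges) == 1  # >= semantics: even disjoint pairs link

    def test_duplicates_plus_disjoint(self):
        sets = [pset("P1", "ABC"), pset("P2", "ABC"), pset("P3", "XYZ")]
        net = build_similarity_network(sets, cutoff=0.3)
        assert len(net.edges) == 1
        assert net.nodes == ["P1", "P2", "P3"]


class TestMcl:
    def test_two_cliques(self):
        sets = [
            pset("A1", "abc"), pset("A2", "abd"), pset("A3", "acd"),
            pset("B1", "xyz"), pset("B2", "xyw"), pset("B3", "xzw"),
        ]
        net = build_similarity_network(sets, cutoff=0.3)
        clusters = mcl_cluster(net)
        groups = {frozenset(m) for m in clusters.clusters.values()}
        assert groups == {frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"})}

    def test_all_singletons(self):
        net = SimilarityNetwork(nodes=["P1", "P2", "P3"], edges=[])
        clusters = mcl_cluster(net)
        assert clusters.n_clusters == 3
        assert all(len(m) == 1 for m in clusters.clusters.values())

    def test_barbell_splits_at_weak_bridge(self):
        # two triangles (internal weight 1.0) joined by a single 0.31 edge
        net = SimilarityNetwork(
            nodes=["a1", "a2", "a3", "b1", "b2", "b3"],
            edges=[
                ("a1", "a2", 1.0), ("a1", "a3", 1.0), ("a2", "a3", 1.0),
                ("b1", "b2", 1.0), ("b1", "b3", 1.0), ("b2", "b3", 1.0),
                ("a3", "b1", 0.31),
            ],
        )
        clusters = mcl_cluster(net, inflation=2.0)
        groups = {frozenset(m) for m in clusters.clusters.values()}
        assert groups == {frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"})}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        sets = [
            pset(f"P{i:02d}", rng.choice(list("abcdefghijkl"), size=5, replace=False))
            for i in range(12)
        ]
        net = build_similarity_network(sets, cutoff=0.3)
        clusters = mcl_cluster(net)
        members = sorted(pid for m in clusters.clusters.values() for pid in m)
        assert members == sorted(net.nodes)  # exactly once each

    def test_determinism(self):
        sets = [pset("P1", "abc"), pset("P2", "abd"), pset("P3", "xyz")]
        net = build_similarity_network(sets, cutoff=0.3)
        a = mcl_cluster(net).clusters
        b = mcl_cluster(net).clusters
        assert a == b

    def test_representative_lowest_fdr(self):
        sets = [pset("P1", "abc"), pset("P2", "abd")]
        net = build_similarity_network(sets, cutoff=0.3)
        results = [result("P1", 0.005), result("P2", 0.001)]
        clusters = mcl_cluster(net, results=results)
        assert list(clusters.representative.values()) == ["P2"]

    def test_empty_network(self):
        clusters = mcl_cluster(SimilarityNetwork(nodes=[], edges=[]))
        assert clusters.n_clusters == 0

    def test_raising_cutoff_never_merges_components(self):
        rng = np.random.default_rng(5)
        sets = [
            pset(f"P{i:02d}", rng.choice(list("abcdefghijklmnop"), size=6, replace=False))
            for i in range(10)
        ]
        import networkx as nx

        comp_at = {}
        for cutoff in (0.2, 0.4, 0.6):
            net = build_similarity_network(sets, cutoff=cutoff)
            g = nx.Graph()
            g.add_nodes_from(net.nodes)
            g.add_edges_from((a, b) for a, b, _ in net.edges)
            comp_at[cutoff] = list(nx.connected_components(g))
        for lo, hi in [(0.2, 0.4), (0.4, 0.6)]:
            for comp in comp_at[hi]:
                # every high-cutoff component sits inside one low-cutoff component
                assert any(comp <= big for big in comp_at[lo])


class TestSelectDisplay:
    def test_few_clusters_all_shown(self):
        sets = [pset(f"P{i}", [f"g{i}"]) for i in range(5)]
        net = build_similarity_network(sets, cutoff=0.3)
        results = [result(f"P{i}", 0.001 * (i + 1)) for i in range(5)]
        clusters = mcl_cluster(net, results=results)
        disp = select_display(clusters, results)
        assert len(disp.clusters) == 5

    def test_thirty_clusters_top_twenty(self):
        sets = [pset(f"P{i:02d}", [f"g{i}"]) for i in range(30)]
        net = build_similarity_network(sets, cutoff=0.3)
        results = [result(f"P{i:02d}", 0.001 * (i + 1)) for i in range(30)]
        clusters = mcl_cluster(net, results=results)
        disp = select_display(clusters, results)
        assert len(disp.clusters) == 20
        shown_fdrs = [c["fdr"] for c in disp.clusters]
        assert shown_fdrs == sorted(shown_fdrs)
        assert max(shown_fdrs) <= 0.020 + 1e-12  # lowest-FDR 20 of 30

    def test_large_cluster_trimmed_to_ten(self):
        sets = [pset(f"P{i:02d}", "abcde") for i in range(14)]  # identical gene sets
        net = build_similarity_network(sets, cutoff=0.3)
        results = [result(f"P{i:02d}", 0.0001 * (i + 1)) for i in range(14)]
        clusters = mcl_cluster(net, results=results)
        assert clusters.n_clusters == 1
        disp = select_display(clusters, results)
        assert len(disp.clusters[0]["members"]) == 10
        assert disp.clusters[0]["members"][0] == "P00"
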