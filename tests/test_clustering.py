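from __future__ import annotations

import random

import pytest

from plastfam.clustering import (
    ClusterParams,
    cluster,
    cut_low_edges,
    max_spanning_forest,
    minimize_paralogs,
)
from plastfam.genome_io import ProteinRecord
from plastfam.similarity import SimilarityEdge

from _oracles import max_forest_weight_bruteforce
from conftest import random_weighted_instance


def E(a, b, w):
    return SimilarityEdge(a, b, w)


def forest_weight(forest):
    return sum(e.weight for e in forest.retained_edges)


class TestMaxSpanningForest:
    def test_k4_example_matches_exhaustive_enumeration(self):
        """Kruskal picks {ab, bc, cd} (weight 2.4) out of the 16 trees of K4."""
        nodes = ["s|a", "s|b", "s|c", "s|d"]
        edges = [
            E("s|a", "s|b", 0.9), E("s|b", "s|c", 0.8), E("s|c", "s|d", 0.7),
            E("s|a", "s|c", 0.5), E("s|b", "s|d", 0.4), E("s|a", "s|d", 0.1),
        ]
        forest = max_spanning_forest(nodes, edges)
        assert {e.pair for e in forest.retained_edges} == {
            ("s|a", "s|b"), ("s|b", "s|c"), ("s|c", "s|d")
        }
        assert forest_weight(forest) == pytest.approx(2.4)
        brute = max_forest_weight_bruteforce(nodes, [(e.a, e.b, e.weight) for e in edges])
        assert forest_weight(forest) == pytest.approx(brute)

    def test_single_node_is_singleton_component(self):
        forest = max_spanning_forest(["s|a"], [])
        assert forest.retained_edges == () and set(forest.component_of) == {"s|a"}

    def test_equal_weights_resolved_by_lexicographic_pair(self):
        nodes = ["s|a", "s|b", "s|c"]
        edges = [E("s|a", "s|b", 0.5), E("s|a", "s|c", 0.5), E("s|b", "s|c", 0.5)]
        forest = max_spanning_forest(nodes, edges)
        assert {e.pair for e in forest.retained_edges} == {("s|a", "s|b"), ("s|a", "s|c")}

    def test_unknown_edge_endpoint_rejected(self):
        with pytest.raises(ValueError):
            max_spanning_forest(["s|a"], [E("s|a", "s|b", 0.5)])

    def test_matches_enumeration_on_random_small_graphs(self):
        rng = random.Random(11)
        for _ in range(40):
            n = rng.randint(2, 7)
            nodes = [f"s|n{i}" for i in range(n)]
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        edges.append(E(nodes[i], nodes[j], round(rng.random(), 3)))
            forest = max_spanning_forest(nodes, edges)
            brute = max_forest_weight_bruteforce(nodes, [(e.a, e.b, e.weight) for e in edges])
            assert forest_weight(forest) == pytest.approx(brute)


class TestCutLowEdges:
    def test_chain_splits_below_threshold(self):
        forest = max_spanning_forest(
            ["s|a", "s|b", "s|c"], [E("s|a", "s|b", 0.9), E("s|b", "s|c", 0.5)]
        )
        cut = cut_low_edges(forest, 0.6)
        comps = {frozenset(c) for c in cut.components()}
        assert comps == {frozenset({"s|a", "s|b"}), frozenset({"s|c"})}

    def test_zero_threshold_is_identity(self):
        forest = max_spanning_forest(["s|a", "s|b"], [E("s|a", "s|b", 0.3)])
        assert cut_low_edges(forest, 0.0).retained_edges == forest.retained_edges

    def test_threshold_one_keeps_only_exact_duplicates(self):
        rng = random.Random(3)
        nodes, edges = random_weighted_instance(rng, edge_prob=0.7)
        edges.append(E("SP0|P0", "SP1|P0", 1.0))
        forest = max_spanning_forest(nodes, edges)
        survivors = cut_low_edges(forest, 1.0).retained_edges
        assert all(e.weight == 1.0 for e in survivors)
        assert {e.weight for e in forest.retained_edges if e.weight == 1.0} <= {e.weight for e in survivors}


class TestMinimizeParalogs:
    def test_strong_path_keeps_same_species_pair(self):
        """Two same-species proteins stay together when the path floor >= R."""
        forest = max_spanning_forest(
            ["spX|a1", "spY|b", "spX|a2"],
            [E("spX|a1", "spY|b", 0.9), E("spY|b", "spX|a2", 0.65)],
        )
        out = minimize_paralogs(forest, 0.6)
        assert len(out.components()) == 1

    def test_weak_path_edge_is_cut(self):
        forest = max_spanning_forest(
            ["spX|a1", "spY|b", "spX|a2"],
            [E("spX|a1", "spY|b", 0.9), E("spY|b", "spX|a2", 0.55)],
        )
        out = minimize_paralogs(forest, 0.6)
        comps = {frozenset(c) for c in out.components()}
        assert comps == {frozenset({"spX|a1", "spY|b"}), frozenset({"spX|a2"})}

    def test_threshold_above_all_weights_forbids_all_paralogs(self):
        """With R above every edge weight no component keeps two same-species proteins."""
        rng = random.Random(23)
        for _ in range(30):
            nodes, edges = random_weighted_instance(rng, n_species=3, n_per_species=4, edge_prob=0.4)
            forest = max_spanning_forest(nodes, edges)
            out = minimize_paralogs(forest, 1.0)  # weights are rounded to 3 dp < 1.0
            for comp in out.components():
                species = [m.split("|")[0] for m in comp]
                assert len(species) == len(set(species))


def _identical_proteins():
    return [
        ProteinRecord(protein_id="p1", species_id="A", sequence="MKVLAWGHEE"),
        ProteinRecord(protein_id="p2", species_id="B", sequence="MKVLAWGHEE"),
        ProteinRecord(protein_id="p3", species_id="C", sequence="MKVLAWGHEE"),
    ]


class TestClusterPipeline:
    def test_identical_proteins_form_one_family(self):
        from plastfam.similarity import build_edges

        recs = _identical_proteins()
        cs = cluster(recs, build_edges(recs), ClusterParams())
        assert len(cs.clusters) == 1 and cs.clusters[0].size == 3
        assert cs.clusters[0].cluster_id == "p1"

    def test_all_weak_pairs_yield_singletons(self):
        recs = _identical_proteins()
        edges = [E(recs[0].key, recs[1].key, 0.2), E(recs[1].key, recs[2].key, 0.3)]
        cs = cluster(recs, edges, ClusterParams(H=0.6))
        assert len(cs.clusters) == 3 and all(c.size == 1 for c in cs.clusters)

    def test_partition_property(self):
        rng = random.Random(5)
        nodes, edges = random_weighted_instance(rng, n_species=5, n_per_species=4)
        recs = [
            ProteinRecord(protein_id=n.split("|")[1], species_id=n.split("|")[0], sequence="MKV")
            for n in nodes
        ]
        cs = cluster(recs, edges, ClusterParams())
        members = [m for c in cs.clusters for m in c.members]
        assert sorted(members) == sorted(nodes)

    def test_deterministic_under_input_permutation(self):
        rng = random.Random(9)
        nodes, edges = random_weighted_instance(rng, n_species=5, n_per_species=4)
        recs = [
            ProteinRecord(protein_id=n.split("|")[1], species_id=n.split("|")[0], sequence="MKV")
            for n in nodes
        ]
        cs1 = cluster(recs, edges, ClusterParams())
        recs2, edges2 = recs[:], edges[:]
        rng.shuffle(recs2)
        rng.shuffle(edges2)
        cs2 = cluster(recs2, edges2, ClusterParams())
        assert [(c.cluster_id, c.members) for c in cs1.clusters] == [
            (c.cluster_id, c.members) for c in cs2.clusters
        ]

    def test_raising_H_never_merges_families(self):
        rng = random.Random(13)
        nodes, edges = random_weighted_instance(rng, n_species=4, n_per_species=4, edge_prob=0.6)
        recs = [
            ProteinRecord(protein_id=n.split("|")[1], species_id=n.split("|")[0], sequence="MKV")
            for n in nodes
        ]
        counts = [
            len(cluster(recs, edges, ClusterParams(H=h, R=0.0)).clusters)
            for h in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
        ]
        assert counts == sorted(counts)

    def test_no_mutual_best_hit_dependence(self):
        """Deleting a protein's single best hit does not orphan it."""
        from plastfam.clustering import ClusterSet

        x = ProteinRecord(protein_id="x", species_id="A", sequence="MKV")
        y = ProteinRecord(protein_id="y", species_id="B", sequence="MKV")
        z = ProteinRecord(protein_id="z", species_id="C", sequence="MKV")
        edges_full = [E(x.key, y.key, 0.95), E(x.key, z.key, 0.8), E(y.key, z.key, 0.7)]
        with_best = cluster([x, y, z], edges_full, ClusterParams())
        assert len(with_best.clusters) == 1
        # remove y (x's best hit) entirely; x keeps its strong link to z
        without_best = cluster([x, z], [E(x.key, z.key, 0.8)], ClusterParams())
        assert len(without_best.clusters) == 1
        assert without_best.clusters[0].members == frozenset({x.key, z.key})


class TestClusterParams:
    def test_r_defaults_to_h(self):
        assert ClusterParams(H=0.7).R == 0.7

    @pytest.mark.parametrize("kwargs", [dict(H=0.4, L=0.5), dict(H=1.2), dict(R=-0.1)])
    def test_invalid_ranges_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClusterParams(**kwargs)
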