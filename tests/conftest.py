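from __future__ import annotations

import random

import pytest
from hypothesis import settings

from plastfam.clustering import Cluster, ClusterParams, ClusterSet
from plastfam.datasets import load_panel
from plastfam.similarity import SimilarityEdge

settings.register_profile("deterministic", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def moeb_panel(tmp_path_factory):
    """The 12-species moeB neighborhood fixture panel, loaded via genome_io."""
    tmp = tmp_path_factory.mktemp("panel")
    plastomes, proteins = load_panel(tmp)
    return plastomes, proteins


@pytest.fixture(scope="session")
def panel_clusters(moeb_panel):
    """Family partition of the panel proteins under default parameters."""
    from plastfam.clustering import cluster
    from plastfam.similarity import build_edges

    _, proteins = moeb_panel
    edges = build_edges(proteins)
    return cluster(proteins, edges, ClusterParams())


def random_weighted_instance(rng: random.Random, n_species=4, n_per_species=3, edge_prob=0.5):
    """A random node set (with species structure) plus random weighted edges."""
    nodes = [f"SP{s}|P{p}" for s in range(n_species) for p in range(n_per_species)]
    edges = []
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if rng.random() < edge_prob:
                edges.append(SimilarityEdge(u, v, round(rng.uniform(0.05, 0.95), 3)))
    return nodes, edges


def random_partition_clusterset(rng: random.Random, n_proteins=40, n_clusters=10, n_species=12) -> ClusterSet:
    """A random valid partition of synthetic protein keys into clusters."""
    keys = [f"SP{rng.randrange(n_species):02d}|P{i:03d}" for i in range(n_proteins)]
    assignment: dict[int, set[str]] = {}
    for k in keys:
        assignment.setdefault(rng.randrange(n_clusters), set()).add(k)
    clusters = tuple(
        Cluster(cluster_id=f"C{cid:02d}", members=frozenset(m))
        for cid, m in assignment.items()
        if m
    )
    return ClusterSet(clusters=clusters, params=ClusterParams())
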