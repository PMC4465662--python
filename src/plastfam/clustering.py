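"""Paralog-minimizing spanning-forest clustering of the protein graph.

The pipeline partitions proteins into orthologous families in three
deterministic steps:

1. a maximum-weight spanning forest of the similarity graph (Kruskal on
   descending weight, ties broken by lexicographic endpoint pair);
2. removal of retained tree edges with weight below the retention
   threshold ``H`` — each surviving subtree is a candidate family;
3. greedy paralog minimization: while a component holds two proteins of
   the same species whose unique tree path contains an edge weaker than
   the paralog-retention threshold ``R``, the globally weakest such edge
   is cut.  Same-species pairs whose weakest connecting edge is at least
   ``R`` are kept together, which is how genuine recent duplicates
   survive as within-family paralogs.

This deliberately avoids any mutual-best-hit criterion: a protein stays
in its family through any sufficiently strong tree path, not only via a
reciprocal top hit.  The dominant cost is the O(n^2) all-pairs edge
construction upstream; forest construction is O(E log E).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .genome_io import ProteinRecord
from .similarity import SimilarityEdge


def species_of(key: str) -> str:
    """Species component of a canonical ``species|protein_id`` key."""
    return key.split("|", 1)[0]


def protein_id_of(key: str) -> str:
    return key.split("|", 1)[1]


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds steering the partition.

    H
        tree-edge retention threshold: forest edges weaker than H are
        cut after forest construction (default 0.6).
    L
        graph-edge admission bound: only pairwise similarities strictly
        above L become graph edges (default 0).
    R
        paralog-retention threshold: a same-species pair stays in one
        family only if every edge on its tree path is >= R.  Defaults to
        H, leaving a single free similarity scale.
    """

    H: float = 0.6
    L: float = 0.0
    R: float | None = None

    def __post_init__(self) -> None:
        if self.R is None:
            object.__setattr__(self, "R", self.H)
        if not (0.0 <= self.L <= self.H <= 1.0):
            raise ValueError("require 0 <= L <= H <= 1")
        if not (0.0 <= self.R <= 1.0):
            raise ValueError("require 0 <= R <= 1")


@dataclass(frozen=True)
class SpanningForest:
    """An acyclic subgraph of the protein graph plus its component map."""

    nodes: tuple[str, ...]
    retained_edges: tuple[SimilarityEdge, ...]
    component_of: Mapping[str, int] = field(hash=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.component_of is None:
            object.__setattr__(self, "component_of", _component_map(self.nodes, self.retained_edges))
        n_components = len(set(self.component_of.values()))
        if len(self.retained_edges) != len(self.nodes) - n_components:
            raise ValueError("edge set is not a forest over the given nodes")

    def components(self) -> list[frozenset[str]]:
        by_id: dict[int, set[str]] = {}
        for node, cid in self.component_of.items():
            by_id.setdefault(cid, set()).add(node)
        return [frozenset(s) for _, s in sorted(by_id.items())]


def _component_map(nodes: Sequence[str], edges: Iterable[SimilarityEdge]) -> dict[str, int]:
    parent = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        ra, rb = find(e.a), find(e.b)
        if ra != rb:
            parent[ra] = rb
    # stable component ids: index of the lexicographically smallest member
    roots: dict[str, list[str]] = {}
    for n in nodes:
        roots.setdefault(find(n), []).append(n)
    ordered = sorted(min(members) for members in roots.values())
    rank = {m: i for i, m in enumerate(ordered)}
    return {n: rank[min(roots[find(n)])] for n in nodes}


def max_spanning_forest(nodes: Iterable[str], edges: Sequence[SimilarityEdge]) -> SpanningForest:
    """Maximum total-weight spanning forest (Kruskal, deterministic ties).

    Edges are taken in descending weight; equal weights are resolved by
    the lexicographically smaller (a, b) endpoint pair, which makes the
    result independent of input order.
    """
    node_tuple = tuple(sorted(set(nodes)))
    known = set(node_tuple)
    for e in edges:
        if e.a not in known or e.b not in known:
            raise ValueError(f"edge ({e.a}, {e.b}) references an unknown node")

    parent = {n: n for n in node_tuple}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    retained: list[SimilarityEdge] = []
    for e in sorted(edges, key=lambda e: (-e.weight, e.pair)):
        ra, rb = find(e.a), find(e.b)
        if ra != rb:
            parent[ra] = rb
            retained.append(e)
    return SpanningForest(nodes=node_tuple, retained_edges=tuple(retained))


def cut_low_edges(forest: SpanningForest, H: float) -> SpanningForest:
    """Drop retained edges with weight strictly below ``H``."""
    kept = tuple(e for e in forest.retained_edges if e.weight >= H)
    return SpanningForest(nodes=forest.nodes, retained_edges=kept)


def _paralog_cut_candidates(graph: nx.Graph, component: set[str], R: float) -> list[tuple[float, tuple[str, str]]]:
    """Weakest path edges of same-species pairs in one tree component."""
    by_species: dict[str, list[str]] = {}
    for node in component:
        by_species.setdefault(species_of(node), []).append(node)
    candidates: list[tuple[float, tuple[str, str]]] = []
    for members in by_species.values():
        if len(members) < 2:
            continue
        members.sort()
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                path = nx.shortest_path(graph, u, v)
                weakest = min(
                    ((graph[x][y]["weight"], tuple(sorted((x, y)))) for x, y in zip(path, path[1:])),
                )
                if weakest[0] < R:
                    candidates.append(weakest)
    return candidates


def minimize_paralogs(forest: SpanningForest, R: float) -> SpanningForest:
    """Greedily cut weak edges until no same-species pair is weakly linked.

    While any component contains two proteins of one species whose tree
    path has minimum edge weight < R, the globally smallest such edge is
    cut (ties by lexicographic endpoint pair).  Pairs whose weakest path
    edge is >= R remain together.
    """
    graph = nx.Graph()
    graph.add_nodes_from(forest.nodes)
    for e in forest.retained_edges:
        graph.add_edge(e.a, e.b, weight=e.weight)

    cut: set[tuple[str, str]] = set()
    # a cut only splits one component, so candidates of untouched
    # components are stable between rounds; cache them per component key
    cache: dict[frozenset[str], list[tuple[float, tuple[str, str]]]] = {}
    while True:
        candidates: list[tuple[float, tuple[str, str]]] = []
        fresh: dict[frozenset[str], list[tuple[float, tuple[str, str]]]] = {}
        for comp in nx.connected_components(graph):
            comp = frozenset(comp)
            if comp not in cache:
                cache[comp] = _paralog_cut_candidates(graph, set(comp), R)
            fresh[comp] = cache[comp]
            candidates.extend(cache[comp])
        cache = fresh
        if not candidates:
            break
        _, (u, v) = min(candidates, key=lambda t: (t[0], t[1]))
        graph.remove_edge(u, v)
        cut.add((u, v))
    kept = tuple(e for e in forest.retained_edges if e.pair not in cut)
    return SpanningForest(nodes=forest.nodes, retained_edges=kept)


@dataclass(frozen=True)
class Cluster:
    """One inferred protein family; members are canonical protein keys."""

    cluster_id: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster cannot be empty")

    @property
    def size(self) -> int:
        return len(self.members)

    def species_multiset(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for m in self.members:
            sp = species_of(m)
            counts[sp] = counts.get(sp, 0) + 1
        return counts

    def max_per_species(self) -> int:
        return max(self.species_multiset().values())


@dataclass(frozen=True)
class ClusterSet:
    """A full partition of the input proteins into families."""

    clusters: tuple[Cluster, ...]
    params: ClusterParams

    def __post_init__(self) -> None:
        all_members = [m for c in self.clusters for m in c.members]
        if len(all_members) != len(set(all_members)):
            raise ValueError("clusters overlap: some protein appears twice")
        object.__setattr__(
            self, "clusters", tuple(sorted(self.clusters, key=lambda c: c.cluster_id))
        )

    @property
    def n_proteins(self) -> int:
        return sum(c.size for c in self.clusters)

    def members(self) -> frozenset[str]:
        return frozenset(m for c in self.clusters for m in c.members)

    def cluster_by_id(self, cluster_id: str) -> Cluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(f"no cluster with id {cluster_id!r}")

    def cluster_of(self, key: str) -> Cluster:
        for c in self.clusters:
            if key in c.members:
                return c
        raise KeyError(f"protein {key!r} not in any cluster")


def _assign_ids(components: list[frozenset[str]]) -> list[Cluster]:
    # id = lexicographically smallest member protein_id; fall back to the
    # full species|protein key when two components would collide
    named = sorted(
        (min(protein_id_of(m) for m in comp), comp) for comp in components
    )
    ids = [pid for pid, _ in named]
    clusters = []
    for pid, comp in named:
        cid = pid if ids.count(pid) == 1 else min(comp)
        clusters.append(Cluster(cluster_id=cid, members=comp))
    return clusters


def cluster(
    proteins: Sequence[ProteinRecord],
    edges: Sequence[SimilarityEdge],
    params: ClusterParams = ClusterParams(),
) -> ClusterSet:
    """Full partition: spanning forest -> H cut -> paralog minimization."""
    nodes = [p.key for p in proteins]
    forest = max_spanning_forest(nodes, edges)
    forest = cut_low_edges(forest, params.H)
    forest = minimize_paralogs(forest, params.R)
    return ClusterSet(clusters=tuple(_assign_ids(forest.components())), params=params)


def write_groups(clusters: ClusterSet, path: str | Path) -> None:
    """OrthoMCL groups.txt dialect: ``cluster_id: key key ...`` per line."""
    with open(path, "w") as fh:
        for c in clusters.clusters:
            fh.write(f"{c.cluster_id}: " + " ".join(sorted(c.members)) + "\n")


def read_groups(path: str | Path) -> ClusterSet:
    """Read a groups file written by :func:`write_groups`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            cid, _, rest = line.partition(":")
            members = frozenset(rest.split())
            out.append(Cluster(cluster_id=cid.strip(), members=members))
    return ClusterSet(clusters=tuple(out), params=ClusterParams())


def write_clusters_tsv(clusters: ClusterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tspecies_id\tprotein_id\n")
        for c in clusters.clusters:
            for m in sorted(c.members):
                fh.write(f"{c.cluster_id}\t{species_of(m)}\t{protein_id_of(m)}\n")
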