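"""Phylogenetic distributions (profiles) of protein families.

A profile records, over a fixed ordered species set S, the value +1 for
every species in which the family has at least one member and -1
elsewhere.  Families whose profiles coincide are candidate functional
partners — e.g. a gene and the transcription factor that regulates it —
which is the query this module exposes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .clustering import Cluster, ClusterSet, species_of


@dataclass(frozen=True)
class PhyloProfile:
    """Presence (+1) / absence (-1) vector over an ordered species set."""

    species_order: tuple[str, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.species_order):
            raise ValueError("values and species_order lengths differ")
        if any(v not in (1, -1) for v in self.values):
            raise ValueError("profile values must be +1 or -1")
        if len(set(self.species_order)) != len(self.species_order):
            raise ValueError("duplicate species in species_order")

    @property
    def n_present(self) -> int:
        return sum(1 for v in self.values if v == 1)


def profile_of(cluster: Cluster, species_order: Sequence[str]) -> PhyloProfile:
    """Profile of one family: +1 where the species has >= 1 member.

    Presence is binary regardless of paralog count.  A member from a
    species outside ``species_order`` is an error, not silent absence.
    """
    order = tuple(species_order)
    if not order:
        raise ValueError("species_order must be non-empty")
    known = set(order)
    present = set()
    for m in cluster.members:
        sp = species_of(m)
        if sp not in known:
            raise ValueError(f"cluster member species {sp!r} not in species_order")
        present.add(sp)
    return PhyloProfile(order, tuple(1 if sp in present else -1 for sp in order))


def _check_same_order(p: PhyloProfile, q: PhyloProfile) -> None:
    if p.species_order != q.species_order:
        raise ValueError("profiles are defined over different species orders")


def profiles_coincide(p: PhyloProfile, q: PhyloProfile) -> bool:
    """True iff the two profiles agree at every species."""
    _check_same_order(p, q)
    return p.values == q.values


def hamming(p: PhyloProfile, q: PhyloProfile) -> int:
    """Number of species where the two profiles disagree."""
    _check_same_order(p, q)
    return sum(1 for a, b in zip(p.values, q.values) if a != b)


def find_coinciding(
    clusters: ClusterSet, query_id: str, species_order: Sequence[str]
) -> list[str]:
    """Ids of all families whose profile equals the query family's.

    The query itself is excluded; results are sorted by cluster id.
    """
    query = clusters.cluster_by_id(query_id)  # raises KeyError if unknown
    ref = profile_of(query, species_order)
    hits = [
        c.cluster_id
        for c in clusters.clusters
        if c.cluster_id != query_id and profiles_coincide(profile_of(c, species_order), ref)
    ]
    return sorted(hits)


def profile_matrix(clusters: ClusterSet, species_order: Sequence[str] | None = None) -> pd.DataFrame:
    """+1/-1 matrix, rows = families, columns = species (sorted by default)."""
    if species_order is None:
        species_order = sorted({species_of(m) for c in clusters.clusters for m in c.members})
    order = tuple(species_order)
    rows = {
        c.cluster_id: profile_of(c, order).values for c in clusters.clusters
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(order)).sort_index()


def write_profile_matrix(clusters: ClusterSet, path: str | Path) -> None:
    profile_matrix(clusters).to_csv(path, sep="\t", index_label="cluster_id")
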