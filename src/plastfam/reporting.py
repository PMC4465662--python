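"""Database-level statistics and the species-by-family membership matrix.

The headline numbers of an orthology database are the family count, the
nonsingleton count (families with >= 2 proteins), and — because the
clustering explicitly minimizes paralogous content — how many
nonsingleton families are paralog-free (at most one protein per
species) versus carrying two or three same-species proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .clustering import ClusterSet, protein_id_of, species_of


@dataclass(frozen=True)
class StatsSummary:
    n_proteins: int
    n_families: int
    n_nonsingletons: int
    n_paralog_free_nonsingletons: int
    #: max-proteins-per-species within a cluster -> number of clusters
    multiplicity_histogram: tuple[tuple[int, int], ...]

    def histogram(self) -> dict[int, int]:
        return dict(self.multiplicity_histogram)


def cluster_stats(clusters: ClusterSet) -> StatsSummary:
    """Exact counts over a family partition.

    A nonsingleton has >= 2 members; a family is paralog-free when no
    species contributes more than one protein.  Paralog-freeness is
    judged on the final clusters, not on input annotations.
    """
    hist: dict[int, int] = {}
    n_nonsingleton = 0
    n_paralog_free_ns = 0
    for c in clusters.clusters:
        mult = c.max_per_species()
        hist[mult] = hist.get(mult, 0) + 1
        if c.size >= 2:
            n_nonsingleton += 1
            if mult == 1:
                n_paralog_free_ns += 1
    return StatsSummary(
        n_proteins=clusters.n_proteins,
        n_families=len(clusters.clusters),
        n_nonsingletons=n_nonsingleton,
        n_paralog_free_nonsingletons=n_paralog_free_ns,
        multiplicity_histogram=tuple(sorted(hist.items())),
    )


def species_cluster_matrix(clusters: ClusterSet) -> pd.DataFrame:
    """Member-count matrix: rows = families, columns = species (sorted).

    Row sums equal cluster sizes; column sums equal per-species protein
    counts; the grand total equals the number of proteins.
    """
    species = sorted({species_of(m) for c in clusters.clusters for m in c.members})
    data = {}
    for c in clusters.clusters:
        counts = c.species_multiset()
        data[c.cluster_id] = [counts.get(sp, 0) for sp in species]
    df = pd.DataFrame.from_dict(data, orient="index", columns=species)
    return df.sort_index()


def write_stats_json(stats: StatsSummary, path: str | Path) -> None:
    doc = {
        "n_proteins": stats.n_proteins,
        "n_families": stats.n_families,
        "n_nonsingletons": stats.n_nonsingletons,
        "n_paralog_free_nonsingletons": stats.n_paralog_free_nonsingletons,
        "multiplicity_histogram": {str(k): v for k, v in stats.multiplicity_histogram},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_matrix_tsv(clusters: ClusterSet, path: str | Path) -> None:
    species_cluster_matrix(clusters).to_csv(path, sep="\t", index_label="cluster_id")
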