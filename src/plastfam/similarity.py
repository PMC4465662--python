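"""Normalized pairwise protein similarity and the weighted protein graph.

Edge weights are global (Needleman-Wunsch) alignment scores under an
affine gap model, normalized by the smaller of the two self-alignment
scores and clamped into [0, 1]:

    s(a, b) = max(0, NW(a, b) / min(NW(a, a), NW(b, b)))

so that s(a, a) = 1 exactly and the admission bound L and retention
threshold H of the clustering stage live on a common, interpretable
scale.  A gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import AA_ALPHABET, ProteinRecord


@dataclass(frozen=True)
class AlignParams:
    """Scoring scheme for global protein alignment.

    Defaults (BLOSUM62, gap open 11, extend 1) are the community-standard
    protein scoring scheme; all are configurable.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    mode: str = "global"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.mode != "global":
            raise ValueError("only global alignment is supported")


DEFAULT_ALIGN_PARAMS = AlignParams()


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected weighted link between two proteins (keys are canonical).

    Endpoints are stored sorted so that (a, b) and (b, a) are the same
    edge object value.
    """

    a: str
    b: str
    weight: float

    def __post_init__(self) -> None:
        if self.a > self.b:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"edge weight {self.weight} outside [0, 1]")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b)


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # first gapped position pays open + extend; each further one pays extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("cannot align an empty sequence")
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise ValueError(f"invalid amino-acid symbol(s): {', '.join(bad)}")


def align_global(seq_a: str, seq_b: str, params: AlignParams = DEFAULT_ALIGN_PARAMS) -> float:
    """Optimal global alignment score of two protein sequences."""
    _check_sequence(seq_a)
    _check_sequence(seq_b)
    return float(_aligner(params.matrix_name, params.gap_open, params.gap_extend).score(seq_a, seq_b))


def normalized_similarity(
    seq_a: str, seq_b: str, params: AlignParams = DEFAULT_ALIGN_PARAMS
) -> float:
    """Self-score-normalized global similarity in [0, 1]; 1.0 iff identical inputs score maximally."""
    if seq_a == seq_b:
        _check_sequence(seq_a)
        return 1.0
    denom = min(align_global(seq_a, seq_a, params), align_global(seq_b, seq_b, params))
    if denom <= 0:
        return 0.0
    s = align_global(seq_a, seq_b, params) / denom
    return min(1.0, max(0.0, s))


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_edges(
    proteins: Sequence[ProteinRecord],
    params: AlignParams = DEFAULT_ALIGN_PARAMS,
    L: float = 0.0,
    kmer_prefilter: bool = False,
    kmer_size: int = 4,
    min_shared_kmers: int = 1,
) -> list[SimilarityEdge]:
    """All-pairs similarity edges with weight strictly above ``L``.

    Every unordered pair (same-species pairs included) is aligned once;
    the number of alignments is n(n-1)/2.  The optional k-mer prefilter
    skips pairs sharing fewer than ``min_shared_kmers`` words of length
    ``kmer_size``; it is OFF by default, preserving the exact all-pairs
    contract.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins to build a graph")
    keys = [p.key for p in proteins]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (species_id, protein_id) pairs in input")

    self_score = {
        p.key: align_global(p.sequence, p.sequence, params) for p in proteins
    }
    kmers = {p.key: _kmer_set(p.sequence, kmer_size) for p in proteins} if kmer_prefilter else None

    edges: list[SimilarityEdge] = []
    ordered = sorted(proteins, key=lambda p: p.key)
    for pa, pb in itertools.combinations(ordered, 2):
        if kmers is not None and len(kmers[pa.key] & kmers[pb.key]) < min_shared_kmers:
            continue
        if pa.sequence == pb.sequence:
            w = 1.0
        else:
            denom = min(self_score[pa.key], self_score[pb.key])
            if denom <= 0:
                w = 0.0
            else:
                w = min(1.0, max(0.0, align_global(pa.sequence, pb.sequence, params) / denom))
        if w > L:
            edges.append(SimilarityEdge(pa.key, pb.key, w))
    return edges


def write_edges_tsv(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    """Export the edge list as TSV (protein_a, protein_b, weight to 6 dp)."""
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\tweight\n")
        for e in sorted(edges, key=lambda e: e.pair):
            fh.write(f"{e.a}\t{e.b}\t{e.weight:.6f}\n")
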