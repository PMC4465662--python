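"""Genomic-neighborhood and candidate-promoter reasoning on plastomes.

Three geometric analyses support regulatory case studies of plastid
genes such as *moeB*:

* rendering the annotated neighborhood upstream of a gene in a compact
  dialect — upstream-to-center gene names joined by ``-``, genes on the
  strand opposite the center wrapped in parentheses, e.g.
  ``(trnW)-ORF75-moeB``;
* detecting divergent (antidirected) adjacent gene pairs and their
  shared intergenic interval: when an actively transcribed gene sits
  head-to-head with another, RNA-polymerase competition makes that
  interval the natural candidate zone for the weaker gene's promoter
  and activator binding sites;
* scanning upstream regions for {A,T}-rich windows that may act as
  -10 promoter boxes in the AT-rich plastid background.

The scanner is a deliberate simplification: it flags composition only
and knows nothing about sigma-factor-specific promoter models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .genome_io import GeneFeature, Plastome

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContextString:
    """Rendered upstream neighborhood of a gene (outermost feature first)."""

    center_gene: str
    rendering: str
    upstream_exhausted: bool = False

    def __post_init__(self) -> None:
        if not self.rendering.endswith(self.center_gene):
            raise ValueError("rendering must end with the center gene")


@dataclass(frozen=True)
class DivergentPair:
    """Two antidirected adjacent genes and their shared intergenic interval."""

    gene_a: GeneFeature
    gene_b: GeneFeature
    intergenic_start: int
    intergenic_end: int

    def __post_init__(self) -> None:
        if self.gene_a.strand == self.gene_b.strand:
            raise ValueError("a divergent pair requires opposite strands")
        if self.intergenic_end < self.intergenic_start:
            raise ValueError("intergenic interval must be non-negative")

    @property
    def gap(self) -> int:
        return self.intergenic_end - self.intergenic_start


@dataclass(frozen=True)
class ScanHit:
    """One window position meeting the A+T composition threshold."""

    start: int
    window: int
    at_fraction: float


@dataclass(frozen=True)
class UpstreamRegion:
    """Extracted 5'-flanking sequence in the gene's reading orientation."""

    sequence: str
    start: int
    end: int
    truncated: bool = False


def _unique_feature(plastome: Plastome, gene_name: str) -> GeneFeature:
    hits = plastome.features_named(gene_name)
    if not hits:
        raise ValueError(f"gene {gene_name!r} not found on {plastome.replicon_id}")
    if len(hits) > 1:
        raise ValueError(f"gene {gene_name!r} is not unique on {plastome.replicon_id}")
    return hits[0]


def neighborhood(plastome: Plastome, gene_name: str, k: int) -> ContextString:
    """Render the k nearest upstream features of ``gene_name``.

    Upstream is defined in the gene's own reading orientation.  Features
    on the strand opposite the center are parenthesized; the rendering
    lists the outermost feature first and the center gene last.  If the
    replicon is linear and fewer than k upstream features exist, the
    rendering is shortened and flagged ``upstream_exhausted``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    center = _unique_feature(plastome, gene_name)
    others = [f for f in plastome.features if f is not center]

    def upstream_distance(f: GeneFeature) -> int | None:
        if center.strand == "+":
            d = center.start - f.end
        else:
            d = f.start - center.end
        if d >= 0:
            return d
        if plastome.circular:
            return d % plastome.length
        return None

    ranked = sorted(
        ((d, f) for f in others if (d := upstream_distance(f)) is not None),
        key=lambda t: t[0],
    )
    nearest = [f for _, f in ranked[:k]]
    tokens = []
    for f in reversed(nearest):  # outermost first
        name = f.gene_name or f.feature_id
        tokens.append(f"({name})" if f.strand != center.strand else name)
    tokens.append(gene_name)
    return ContextString(
        center_gene=gene_name,
        rendering="-".join(tokens),
        upstream_exhausted=len(nearest) < k,
    )


def find_divergent_pairs(plastome: Plastome, max_gap: int) -> list[DivergentPair]:
    """All adjacent antidirected gene pairs facing a shared interval <= max_gap.

    A divergent pair is a minus-strand feature immediately followed (in
    coordinate order) by a plus-strand feature: both 5'-proximal ends
    face the intergenic interval between them.  On circular replicons
    the wrap-around adjacency (last feature, first feature) is included.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    feats = plastome.features
    pairs: list[DivergentPair] = []
    if len(feats) < 2:
        return pairs

    def consider(left: GeneFeature, right: GeneFeature, gap_start: int, gap_end: int) -> None:
        if left.strand == "-" and right.strand == "+" and 0 <= gap_end - gap_start <= max_gap:
            pairs.append(DivergentPair(left, right, gap_start, gap_end))

    for left, right in zip(feats, feats[1:]):
        consider(left, right, left.end, right.start)
    if plastome.circular:
        last, first = feats[-1], feats[0]
        # wrap interval [last.end, length) + [0, first.start); report its
        # linear origin-side coordinates only when it does not wrap a feature
        gap = (plastome.length - last.end) + first.start
        if last.strand == "-" and first.strand == "+" and 0 <= gap <= max_gap:
            pairs.append(DivergentPair(last, first, last.end, last.end + gap))
    return sorted(pairs, key=lambda p: p.intergenic_start)


def upstream_region(plastome: Plastome, gene_name: str, length: int) -> UpstreamRegion:
    """The ``length`` nt 5' of a gene's start, in reading orientation.

    Minus-strand genes are reverse-complemented.  The region is wrapped
    across the origin on circular replicons and truncated (with a flag)
    at the edge of linear ones.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if plastome.sequence is None:
        raise ValueError(f"no sequence loaded for {plastome.replicon_id}")
    gene = _unique_feature(plastome, gene_name)
    L = plastome.length
    seq = plastome.sequence

    if gene.strand == "+":
        start, end = gene.start - length, gene.start
        if start >= 0:
            return UpstreamRegion(seq[start:end], start, end)
        if plastome.circular:
            return UpstreamRegion(seq[start % L :] + seq[:end], start % L, end)
        return UpstreamRegion(seq[0:end], 0, end, truncated=True)

    start, end = gene.end, gene.end + length
    if end <= L:
        return UpstreamRegion(reverse_complement(seq[start:end]), start, end)
    if plastome.circular:
        return UpstreamRegion(reverse_complement(seq[start:] + seq[: end % L]), start, end % L)
    return UpstreamRegion(reverse_complement(seq[start:L]), start, L, truncated=True)


def scan_at_rich(seq: str, window: int = 10, min_fraction: float = 0.9) -> list[ScanHit]:
    """Every window start where the A+T fraction meets ``min_fraction``.

    Overlapping hits are reported; matching is case-insensitive.  A
    window longer than the sequence yields no hits.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not (0.0 <= min_fraction <= 1.0):
        raise ValueError("min_fraction must lie in [0, 1]")
    s = seq.upper()
    if window > len(s):
        return []
    is_at = [1 if c in "AT" else 0 for c in s]
    count = sum(is_at[:window])
    hits: list[ScanHit] = []
    for start in range(len(s) - window + 1):
        if start > 0:
            count += is_at[start + window - 1] - is_at[start - 1]
        frac = count / window
        if frac >= min_fraction:
            hits.append(ScanHit(start=start, window=window, at_fraction=frac))
    return hits


def write_context_tsv(rows: Iterable[tuple[str, str, ContextString]], path: str | Path) -> None:
    """TSV of (species, replicon, context_string) rows."""
    with open(path, "w") as fh:
        fh.write("species_id\treplicon_id\tcontext\n")
        for species, replicon, ctx in rows:
            fh.write(f"{species}\t{replicon}\t{ctx.rendering}\n")


def write_divergent_pairs_bed(pairs: Iterable[DivergentPair], replicon_id: str, path: str | Path) -> None:
    """BED-like TSV of intergenic intervals (0-based half-open)."""
    with open(path, "w") as fh:
        for p in pairs:
            name = f"{p.gene_a.gene_name or p.gene_a.feature_id}|{p.gene_b.gene_name or p.gene_b.feature_id}"
            fh.write(f"{replicon_id}\t{p.intergenic_start}\t{p.intergenic_end}\t{name}\n")


def write_scan_hits_tsv(hits: Iterable[tuple[str, ScanHit]], path: str | Path) -> None:
    """TSV of (region_id, start, window, at_fraction) rows."""
    with open(path, "w") as fh:
        fh.write("region_id\tstart\twindow\tat_fraction\n")
        for region_id, h in hits:
            fh.write(f"{region_id}\t{h.start}\t{h.window}\t{h.at_fraction:.4f}\n")
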