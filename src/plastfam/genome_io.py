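"""Readers and writers for annotated plastomes and species-tagged proteomes.

The records produced here are the common currency of the whole package:
every protein is identified by the pair ``(species_id, protein_id)``,
rendered as the key ``species_id|protein_id`` in graph nodes and exports.

Coordinates are 0-based half-open throughout; GenBank's 1-based inclusive
intervals are converted at the parsing boundary (Biopython already does
this).  Features that span the origin of a circular replicon are split
into their linear parts, all carrying the same ``feature_id``, so that
interval arithmetic downstream stays linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 canonical residues plus X for anything ambiguous
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

# B/Z/U/O have no uniform column in the common substitution matrices;
# collapse them to X so every scorer sees one ambiguity symbol.
_AMBIGUOUS = str.maketrans("BZUO", "XXXX")

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "other")


def clean_protein_sequence(raw: str) -> str:
    """Uppercase, strip a terminal stop symbol, collapse ambiguity codes.

    Raises ``ValueError`` naming the offending symbol if a character
    outside the 20-letter alphabet (plus X) remains.
    """
    seq = raw.strip().upper().rstrip("*").translate(_AMBIGUOUS)
    if not seq:
        raise ValueError("empty protein sequence")
    bad = sorted(set(seq) - AA_ALPHABET)
    if bad:
        raise ValueError(f"invalid amino-acid symbol(s): {', '.join(bad)}")
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """One plastid-encoded protein.

    ``start``/``end`` are genomic coordinates (0-based half-open) and are
    ``None`` for proteins loaded from bare FASTA, where no annotation
    context exists.
    """

    protein_id: str
    species_id: str
    sequence: str
    replicon_id: str = ""
    gene_name: str = ""
    start: int | None = None
    end: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_protein_sequence(self.sequence))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be set together")
        if self.start is not None:
            if self.start < 0:
                raise ValueError("start must be >= 0")
            if self.end <= self.start:
                raise ValueError("end must exceed start")

    @property
    def key(self) -> str:
        """Canonical node identifier, ``species_id|protein_id``."""
        return f"{self.species_id}|{self.protein_id}"


@dataclass(frozen=True)
class GeneFeature:
    """An annotated feature on a replicon (CDS, tRNA, rRNA or other)."""

    feature_id: str
    gene_name: str
    kind: str
    start: int
    end: int
    strand: str
    linked_protein_id: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError("feature requires 0 <= start < end")
        if self.kind == "tRNA" and self.linked_protein_id:
            raise ValueError("tRNA features cannot link to a protein")


@dataclass(frozen=True)
class Plastome:
    """A plastid replicon: ordered annotation plus (optionally) sequence."""

    species_id: str
    replicon_id: str
    length: int
    circular: bool
    features: tuple[GeneFeature, ...]
    sequence: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "features", tuple(sorted(self.features, key=lambda f: (f.start, f.end)))
        )
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.feature_id} ends at {f.end}, beyond replicon length {self.length}"
                )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length disagrees with declared replicon length")

    def features_named(self, gene_name: str) -> tuple[GeneFeature, ...]:
        return tuple(f for f in self.features if f.gene_name == gene_name)


def normalize_species(organism: str) -> str:
    """Normalize an ORGANISM line to ``Genus_species``."""
    tokens = organism.replace(",", " ").split()
    return "_".join(tokens[:2]) if len(tokens) >= 2 else (tokens[0] if tokens else "unknown")


def _feature_kind(gb_type: str) -> str:
    return gb_type if gb_type in ("CDS", "tRNA", "rRNA") else "other"


def read_genbank(path: str | Path) -> tuple[list[Plastome], list[ProteinRecord]]:
    """Parse a GenBank flat file into plastomes and their protein records.

    One :class:`Plastome` is produced per GenBank record and one
    :class:`ProteinRecord` per CDS feature carrying a ``/translation``.
    CDS features without a translation are skipped with a logged warning.
    """
    path = Path(path)
    plastomes: list[Plastome] = []
    proteins: list[ProteinRecord] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records found in {path}")

    for rec in records:
        species = normalize_species(rec.annotations.get("organism", rec.id))
        replicon = rec.id or rec.name
        circular = rec.annotations.get("topology", "") == "circular"
        try:
            seq = str(rec.seq) if len(rec.seq) else None
        except Exception:  # sequence may be undefined (CONTIG-only records)
            seq = None
        length = len(rec)

        features: list[GeneFeature] = []
        skipped = 0
        cds_index = 0
        for feat in rec.features:
            if feat.type in ("source", "gene"):
                continue
            kind = _feature_kind(feat.type)
            quals = feat.qualifiers
            gene_name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [""])[0]
            strand = "-" if feat.location.strand == -1 else "+"
            linked = ""
            if kind == "CDS":
                cds_index += 1
                protein_id = (quals.get("protein_id") or quals.get("locus_tag") or [f"cds{cds_index}"])[0]
                translation = (quals.get("translation") or [""])[0]
                if translation:
                    linked = protein_id
                    proteins.append(
                        ProteinRecord(
                            protein_id=protein_id,
                            species_id=species,
                            replicon_id=replicon,
                            sequence=translation,
                            gene_name=gene_name,
                            start=int(feat.location.start),
                            end=int(feat.location.end),
                            strand=strand,
                        )
                    )
                else:
                    skipped += 1
            feature_id = linked or (quals.get("locus_tag") or [f"{kind}_{len(features)}"])[0]
            # origin-spanning compound locations become one part per interval
            for part in feat.location.parts:
                features.append(
                    GeneFeature(
                        feature_id=feature_id,
                        gene_name=gene_name,
                        kind=kind,
                        start=int(part.start),
                        end=int(part.end),
                        strand=strand,
                        linked_protein_id=linked,
                    )
                )
        if skipped:
            logger.warning("%s (%s): skipped %d CDS feature(s) lacking a translation", path, replicon, skipped)
        plastomes.append(
            Plastome(
                species_id=species,
                replicon_id=replicon,
                length=length,
                circular=circular,
                features=tuple(features),
                sequence=seq,
            )
        )
    return plastomes, proteins


def read_fasta_proteome(path: str | Path, species_id: str) -> list[ProteinRecord]:
    """Read a protein FASTA, tagging records with ``species_id``.

    A ``species|protein_id`` header prefix overrides the supplied species.
    Duplicate protein ids within one species and empty sequences are errors.
    """
    records: list[ProteinRecord] = []
    seen: set[tuple[str, str]] = set()
    dups: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            sp, pid = header.split("|", 1)
        else:
            sp, pid = species_id, header
        if not str(rec.seq):
            raise ValueError(f"empty sequence for {sp}|{pid} in {path}")
        if (sp, pid) in seen:
            dups.append(f"{sp}|{pid}")
            continue
        seen.add((sp, pid))
        records.append(ProteinRecord(protein_id=pid, species_id=sp, sequence=str(rec.seq)))
    if dups:
        raise ValueError(f"duplicate protein ids in {path}: {', '.join(sorted(dups))}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as normalized FASTA with ``species|protein_id`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.key}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
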