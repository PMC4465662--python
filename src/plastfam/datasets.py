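"""Curated moeB neighborhood panel: twelve red-algal plastome fixtures.

Gene order, strand layout, replicon accessions and protein identifiers
follow the public GenBank annotations of twelve rhodophyte plastomes in
which the molybdopterin-biosynthesis gene *moeB* is encoded.  In most of
them the tryptophanyl-tRNA gene *trnW* sits immediately upstream of
*moeB* on the opposite strand (sometimes separated by a short ORF),
making the shared intergenic interval the natural candidate zone for
the *moeB* promoter; *Porphyridium purpureum* is the known exception,
with *ycf38* and *ORF144* upstream instead.  Every plastome also
carries the plastid-encoded transcription factor *ycf28* (an NtcA
homolog), whose phylogenetic profile matches *moeB*'s across the panel.

All nucleotide sequences, coordinates and peptide sequences here are
SYNTHETIC stand-ins generated deterministically: only the annotation
layout (names, strands, order, accessions) is curated.  The fixtures
exist so that neighborhood rendering, divergent-pair detection,
upstream AT scanning, clustering and profile queries can be exercised
end to end without network access.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genome_io import Plastome, ProteinRecord, read_genbank

#: (gene_name, strand, kind) of the upstream neighbors of moeB,
#: outermost first, as annotated in each plastome.
_TRNW = [("trnW", "-", "tRNA")]
_TRNW_ORF75 = [("trnW", "-", "tRNA"), ("ORF75", "+", "CDS")]


@dataclass(frozen=True)
class MoebLocus:
    species: str  # normalized Genus_species
    organism: str  # ORGANISM line
    replicon: str
    moeb_protein: str
    ycf28_protein: str
    upstream: tuple[tuple[str, str, str], ...]


PANEL: tuple[MoebLocus, ...] = (
    MoebLocus("Porphyra_purpurea", "Porphyra purpurea", "NC_000925", "NP_053945.1", "NP_053952.1", tuple(_TRNW_ORF75)),
    MoebLocus("Porphyridium_purpureum", "Porphyridium purpureum", "NC_023133", "YP_008965710.1", "YP_008965713.1",
              (("ORF144", "-", "CDS"), ("ycf38", "+", "CDS"))),
    MoebLocus("Pyropia_haitanensis", "Pyropia haitanensis", "NC_021189", "YP_007947865.1", "YP_007947872.1", tuple(_TRNW_ORF75)),
    MoebLocus("Pyropia_perforata", "Pyropia perforata", "NC_024050", "YP_009027619.1", "YP_009027626.1", tuple(_TRNW_ORF75)),
    MoebLocus("Pyropia_yezoensis", "Pyropia yezoensis", "NC_007932", "YP_537017.1", "YP_537023.1", tuple(_TRNW)),
    MoebLocus("Cyanidioschyzon_merolae", "Cyanidioschyzon merolae", "NC_004799", "NP_849016.1", "NP_849012.1", tuple(_TRNW)),
    MoebLocus("Cyanidium_caldarium", "Cyanidium caldarium", "NC_001840", "NP_045115.1", "NP_045121.1", tuple(_TRNW)),
    MoebLocus("Calliarthron_tuberculosum", "Calliarthron tuberculosum", "NC_021075", "YP_007878185.1", "YP_007878179.1", tuple(_TRNW)),
    MoebLocus("Chondrus_crispus", "Chondrus crispus", "NC_020795", "YP_007627343.1", "YP_007627337.1", tuple(_TRNW)),
    MoebLocus("Gracilaria_salicornia", "Gracilaria salicornia", "NC_023785", "YP_009019560.1", "YP_009019566.1", tuple(_TRNW)),
    MoebLocus("Gracilaria_tenuistipitata", "Gracilaria tenuistipitata", "NC_006137", "YP_063552.1", "YP_063558.1", tuple(_TRNW)),
    MoebLocus("Grateloupia_taiwanensis", "Grateloupia taiwanensis", "NC_021618", "YP_008144807.1", "YP_008144797.1", tuple(_TRNW)),
)

#: the annotated genomic-context rendering of the moeB neighborhood per
#: species (curated annotation, used as the expected value in checks)
EXPECTED_CONTEXTS: dict[str, str] = {
    "Porphyra_purpurea": "(trnW)-ORF75-moeB",
    "Porphyridium_purpureum": "(ORF144)-ycf38-moeB",
    "Pyropia_haitanensis": "(trnW)-ORF75-moeB",
    "Pyropia_perforata": "(trnW)-ORF75-moeB",
    "Pyropia_yezoensis": "(trnW)-moeB",
    "Cyanidioschyzon_merolae": "(trnW)-moeB",
    "Cyanidium_caldarium": "(trnW)-moeB",
    "Calliarthron_tuberculosum": "(trnW)-moeB",
    "Chondrus_crispus": "(trnW)-moeB",
    "Gracilaria_salicornia": "(trnW)-moeB",
    "Gracilaria_tenuistipitata": "(trnW)-moeB",
    "Grateloupia_taiwanensis": "(trnW)-moeB",
}

PANEL_SPECIES: tuple[str, ...] = tuple(sorted(l.species for l in PANEL))

_AA = "ACDEFGHIKLMNPQRSTVWY"
_PEP_LEN = 80
_TRNA_SPAN = 72
_GAP = 40
_INTERGENIC = 60  # trnW/moeB-side intergenic interval, hosts the AT-rich core
_AT_CORE = "TATAATATAT"


def _template(seed: int) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice(_AA) for _ in range(_PEP_LEN))


_MOEB_TEMPLATE = _template(70)
_YCF28_TEMPLATE = _template(71)
_ORF_TEMPLATES = {"ORF75": _template(72), "ycf38": _template(73), "ORF144": _template(74)}


def _mutate_pep(template: str, rng: random.Random, rate: float = 0.05) -> str:
    out = []
    for c in template:
        if rng.random() < rate:
            out.append(rng.choice([a for a in _AA if a != c]))
        else:
            out.append(c)
    return "".join(out)


def _random_nt(rng: random.Random, n: int) -> str:
    # plastid-like AT-leaning background, but below the scanner threshold
    return "".join(rng.choices("ACGT", weights=[3, 2, 2, 3], k=n))


def build_record(locus: MoebLocus) -> SeqRecord:
    """One synthetic GenBank record mirroring the annotated moeB locus."""
    idx = [l.replicon for l in PANEL].index(locus.replicon)
    rng = random.Random(1000 + idx)

    seq_parts: list[str] = []
    features: list[SeqFeature] = []
    pos = 0

    def filler(n: int) -> None:
        nonlocal pos
        seq_parts.append(_random_nt(rng, n))
        pos += n

    def add_cds(name: str, strand: str, peptide: str, protein_id: str) -> None:
        nonlocal pos
        span = 3 * (len(peptide) + 1)
        features.append(
            SeqFeature(
                FeatureLocation(pos, pos + span, strand=1 if strand == "+" else -1),
                type="CDS",
                qualifiers={"gene": [name], "protein_id": [protein_id], "translation": [peptide]},
            )
        )
        filler(span)

    def add_trna(name: str, strand: str) -> None:
        nonlocal pos
        features.append(
            SeqFeature(
                FeatureLocation(pos, pos + _TRNA_SPAN, strand=1 if strand == "+" else -1),
                type="tRNA",
                qualifiers={"gene": [name], "product": ["tRNA-Trp"]},
            )
        )
        filler(_TRNA_SPAN)

    filler(60)
    for i, (name, strand, kind) in enumerate(locus.upstream):
        if kind == "tRNA":
            add_trna(name, strand)
        else:
            pep = _mutate_pep(_ORF_TEMPLATES[name], rng)
            add_cds(name, strand, pep, f"SYN_{locus.replicon}_{name}")
        if i < len(locus.upstream) - 1:
            filler(_GAP)

    # intergenic interval immediately 5' of moeB, carrying an AT-rich core
    pre = _random_nt(rng, _INTERGENIC - len(_AT_CORE) - 20)
    seq_parts.append(pre + _AT_CORE + _random_nt(rng, 20))
    pos += _INTERGENIC

    add_cds("moeB", "+", _mutate_pep(_MOEB_TEMPLATE, rng), locus.moeb_protein)
    filler(50)
    add_cds("ycf28", "+", _mutate_pep(_YCF28_TEMPLATE, rng), locus.ycf28_protein)
    filler(60)

    record = SeqRecord(
        Seq("".join(seq_parts)),
        id=locus.replicon,
        name=locus.replicon,
        description=f"{locus.organism} plastid, moeB locus (synthetic fixture)",
        features=features,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": locus.organism,
            "source": f"plastid {locus.organism}",
        },
    )
    return record


def write_panel(out_dir: str | Path) -> list[Path]:
    """Write all twelve fixtures as GenBank flat files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for locus in PANEL:
        path = out / f"{locus.replicon}.synthetic.gb"
        with open(path, "w") as fh:
            SeqIO.write(build_record(locus), fh, "genbank")
        paths.append(path)
    return paths


def load_panel(tmp_dir: str | Path) -> tuple[dict[str, Plastome], list[ProteinRecord]]:
    """Materialize the panel on disk and load it back through genome_io.

    Returns plastomes keyed by species id plus the pooled protein list.
    """
    plastomes: dict[str, Plastome] = {}
    proteins: list[ProteinRecord] = []
    for path in write_panel(tmp_dir):
        ps, prots = read_genbank(path)
        for p in ps:
            plastomes[p.species_id] = p
        proteins.extend(prots)
    return plastomes, proteins
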