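"""Synthetic plastid-proteome sets with known family structure.

Emulates what an orthology pipeline sees when fed a lineage's plastid
proteomes: F protein families over N species, with per-family gene
loss, occasional within-species duplication (paralogs), and sequence
divergence at a controlled per-site substitution rate — together with
the ground-truth family labels needed to score cluster recovery.

The model is intentionally minimal: one random template per family;
each species copy substitutes every site independently with probability
``divergence``, drawing uniformly over the 19 alternative residues (no
rate matrix, no indels).  Duplicates diverge from their species copy at
half rate, making the copy-duplicate edge the strongest in its family
and thereby exercising the paralog-retention rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .clustering import ClusterSet
from .genome_io import ProteinRecord, write_fasta

_AA20 = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated proteome set.

    Defaults describe a mid-sized plastid panel: 15 species, 40
    families, 300-residue proteins, 30% per-site divergence of each
    species copy from its family template, 20% gene loss, no
    duplications.
    """

    n_species: int = 15
    n_families: int = 40
    root_length: int = 300
    divergence: float = 0.3
    loss_rate: float = 0.2
    dup_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_families < 1:
            raise ValueError("need n_species >= 2 and n_families >= 1")
        if self.root_length < 1:
            raise ValueError("root_length must be positive")
        for name in ("divergence", "loss_rate", "dup_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth family label per generated protein key."""

    label_of: Mapping[str, str]


def _mutate(template: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly over the other 19 residues."""
    seq = template.copy()
    sites = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in sites:
        choices = _AA20[_AA20 != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return seq


def generate(config: SimConfig) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Simulate one proteome set; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    species_ids = [f"SP{s:03d}" for s in range(config.n_species)]
    for f in range(config.n_families):
        family_id = f"FAM{f:03d}"
        template = _AA20[rng.integers(len(_AA20), size=config.root_length)]
        for s, sp in enumerate(species_ids):
            if rng.random() < config.loss_rate:
                continue
            copy = _mutate(template, config.divergence, rng)
            pid = f"F{f:03d}"
            rec = ProteinRecord(
                protein_id=pid, species_id=sp, sequence=copy.tobytes().decode(), gene_name=family_id
            )
            records.append(rec)
            labels[rec.key] = family_id
            if rng.random() < config.dup_rate:
                dup = _mutate(copy, config.divergence / 2.0, rng)
                rec_d = ProteinRecord(
                    protein_id=f"{pid}d",
                    species_id=sp,
                    sequence=dup.tobytes().decode(),
                    gene_name=family_id,
                )
                records.append(rec_d)
                labels[rec_d.key] = family_id
    if not records:
        raise ValueError("configuration produced zero proteins (loss_rate too high?)")
    return records, SyntheticTruth(label_of=labels)


def adjusted_rand_index(truth: SyntheticTruth, predicted: ClusterSet) -> float:
    """Adjusted Rand index between the true labels and a predicted partition."""
    truth_keys = set(truth.label_of)
    pred_keys = predicted.members()
    if truth_keys != pred_keys:
        missing = truth_keys ^ pred_keys
        raise ValueError(f"protein universes differ (e.g. {sorted(missing)[:3]})")
    keys = sorted(truth_keys)
    labels_true = [truth.label_of[k] for k in keys]
    pred_label = {m: c.cluster_id for c in predicted.clusters for m in c.members}
    labels_pred = [pred_label[k] for k in keys]
    return float(adjusted_rand_score(labels_true, labels_pred))


def write_truth_tsv(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tfamily\n")
        for key in sorted(truth.label_of):
            fh.write(f"{key}\t{truth.label_of[key]}\n")


def read_truth_tsv(path: str | Path) -> SyntheticTruth:
    labels: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            key, fam = line.rstrip("\n").split("\t")
            labels[key] = fam
    return SyntheticTruth(label_of=labels)


def write_dataset(config: SimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit proteins.fasta (species|protein headers) and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, truth = generate(config)
    fasta = out / "proteins.fasta"
    tsv = out / "truth.tsv"
    write_fasta(records, fasta)
    write_truth_tsv(truth, tsv)
    return fasta, tsv
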