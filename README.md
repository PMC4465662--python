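# plastfam

Orthologous protein families for plastid (chloroplast) proteomes by
**paralog-minimizing spanning-forest clustering**, with the downstream
analyses that make such a family database useful for regulatory case
studies: phylogenetic-profile coincidence queries, genomic-neighborhood
rendering, divergent-gene (head-to-head) promoter-zone detection, and
AT-rich upstream window scanning.

It is aimed at comparative genomicists working with panels of small,
gene-dense organellar genomes — e.g. red algae, taxa with
rhodophyte-derived secondary/tertiary plastids, and Apicomplexa — where
orthologous families are strongly conserved and paralogy is rare enough
that minimizing it is the right inductive bias.

## Method

Proteins are vertices of a graph weighted by normalized global
similarity

    s(a, b) = max(0, NW(a, b) / min(NW(a, a), NW(b, b))) ∈ [0, 1]

with NW the Needleman–Wunsch score (BLOSUM62, affine gaps 11/1 by
default). Families are the components left after three deterministic
steps:

1. **maximum-weight spanning forest** of all edges with `s > L`
   (Kruskal, descending weight, lexicographic tie-breaks);
2. **threshold cut**: tree edges with `s < H` are removed
   (default `H = 0.6`, `L = 0`);
3. **paralog minimization**: while two same-species proteins share a
   component via a tree path whose weakest edge is `< R` (default
   `R = H`), that weakest edge is cut; stronger same-species pairs are
   kept as genuine within-family paralogs.

No mutual-best-hit criterion is involved; a protein stays in its family
through any sufficiently strong path. Complexity is dominated by the
O(n²) all-pairs alignment stage. See `docs/methods.md` for the full
model, parameter semantics and limitations.

## Worked example

Simulate a small panel with known families, cluster it, and read the
summary (`plastfam simulate` writes a FASTA whose headers carry
`species|protein` keys plus a ground-truth table):

```console
$ plastfam simulate --species 6 --families 8 --root-length 120 \
      --divergence 0.1 --loss 0.2 --seed 42 --out sim
wrote sim/proteins.fasta and sim/truth.tsv
$ plastfam cluster --fasta sim/proteins.fasta --H 0.6 --L 0 --out run
INFO plastfam: clustering 37 proteins (H=0.6 L=0 R=0.6, BLOSUM62 11/1)
INFO plastfam: similarity graph: 70 edges above L
INFO plastfam: 8 families, 8 nonsingletons
8 families (8 nonsingletons) -> run
$ cat run/stats.json
{
  "n_proteins": 37,
  "n_families": 8,
  "n_nonsingletons": 8,
  "n_paralog_free_nonsingletons": 8,
  "multiplicity_histogram": {
    "1": 8
  }
}
```

All 8 planted families are recovered from the 37 surviving proteins
(6 species × 8 families minus ~20% simulated gene loss); every family
is a nonsingleton and paralog-free, as expected with duplication
disabled, and `run/groups.txt` lists the memberships:

```
F000: SP000|F000 SP001|F000 SP002|F000 SP003|F000 SP004|F000 SP005|F000
F001: SP000|F001 SP001|F001 SP002|F001 SP003|F001 SP005|F001
```

The package also ships a curated twelve-plastome fixture panel of the
red-algal *moeB* neighborhood (annotation layout from public GenBank
records; sequences synthetic). On it, neighborhood rendering produces
the annotated context strings such as `(trnW)-ORF75-moeB`, and the
profile query shows that the *moeB* family coincides with exactly one
other family — the *ycf28* transcription factor:

```console
$ plastfam context --genbank NC_000925.synthetic.gb --gene moeB --k 2
Porphyra_purpurea	NC_000925	(trnW)-ORF75-moeB
$ plastfam profiles --groups run/groups.txt --query <moeB-family-id>
<ycf28-family-id>
```

Other subcommands: `stats` (summarize a groups file), `scan-at`
(AT-rich windows upstream of a gene).

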