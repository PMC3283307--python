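# synteams

Detection of unordered, gap-tolerant, paralog-aware conserved gene clusters
across multiple genomes, and their use to refine an existing
homologous-family classification into orthologous and paralogous subgroups.

Gene families built from sequence similarity alone routinely lump orthologs
(related by speciation, usually function-retaining) together with paralogs
(related by duplication). Positional conservation helps tell them apart:
genes that sit in the same conserved chromosomal neighborhood across species
are far more likely to be orthologous. `synteams` implements a sliding-window
synteny-team method for comparative genomicists who already have a family
classification (e.g. from clustering protein similarities) and per-species
gene orders, and want to subdivide each family by neighborhood conservation.

## The model

Each chromosome is an ordered sequence of genes `g_i = (p_i, f_i)` with
1-based integer positions `p_i` and family labels `f_i` from an alphabet Σ
(unassigned genes, written `*`, occupy positions but are not in Σ). The
distance between two genes on one chromosome is Δ(g_i, g_j) = |p_i − p_j|.
For a window parameter δ:

- a **δ-segment** is a gene set in which every pair satisfies Δ < δ
  (equivalently, its position span is < δ); gene order and orientation
  inside a segment are irrelevant;
- a family set Σ′ is a **δ-subset** of a chromosome if some δ-segment
  induces exactly Σ′; every such segment is a *witness*;
- Σ′ is a **δ-cluster** if it is a δ-subset on at least two chromosomes; its
  witness S is the union of all genes in witnessing segments;
- a **δ-synteny** is a maximal δ-cluster: Σ′ is absorbed into Σ ⊋ Σ′ when
  Σ's witness covers every witness gene of Σ′;
- a **δ-zone** is a union of syntenies transitively connected through
  witness overlaps of size ≥ 2.

Two syntenies sharing exactly **one** witness gene form a *weak bond*: one
shared (typically paralogous) gene is weak evidence, so the bond is resolved
against a total species order ≺ given by relative speciation time
(`a ≺ b` when species b diverged earlier). The larger witness S_i keeps the
orthologous reading; the smaller S_j loses the bond gene g and
S_j \ {g} is kept as a paralogous synteny. If the smaller side contains a
witness from a species older than g's, the topology is evolutionarily
implausible and no agglomeration across the bond is accepted.

Finally each family is refined: the orthologous zone carrying most of its
witnesses becomes its orthologous subgroup, paralogous zones disjoint from
it become paralogous subgroups, and uncovered members fall back to
singletons. Paralogous tandem copies inside one window are kept in the same
witness set, so tandem arrays do not break clusters.

## Worked example

Two chromosomes around family `f8`, with `s3` having diverged more recently
than `s2`, scanned at δ = 3:

```python
from synteams import parse_compact_notation, GenomeSet, SpeciesOrder, syns_run

c2 = parse_compact_notation("* f5 * * f3 f6 f4 f2 f8", "s2", "c2")
c3 = parse_compact_notation("f4 f8 f4 f7 f8 f8 * f8 f2", "s3", "c3")
genomes = GenomeSet([c2, c3], species_order=SpeciesOrder(("s3", "s2")))

result = syns_run(genomes, delta=3, families=["f8"])
for s in result.syntenies:
    print(sorted(s.families), "witness:", sorted(str(g) for g in s.witness))
for bond in result.weak_bonds:
    print("weak bond witness:", bond.witness_gene)
for z in result.zones:
    print(z.label, sorted(z.families))
for sg in result.partition["f8"]:
    print(sg.subgroup_id, sg.kind, sorted(str(g) for g in sg.genes))
```

prints

```
['f2', 'f8'] witness: ['(8,f2)_s2.c2', '(8,f8)_s3.c3', '(9,f2)_s3.c3', '(9,f8)_s2.c2']
['f4', 'f8'] witness: ['(1,f4)_s3.c3', '(2,f8)_s3.c3', '(3,f4)_s3.c3', '(5,f8)_s3.c3', '(7,f4)_s2.c2', '(9,f8)_s2.c2']
weak bond witness: (9,f8)_s2.c2
paralogous ['f2', 'f8']
orthologous ['f4', 'f8']
f8.1 ortholog ['(2,f8)_s3.c3', '(5,f8)_s3.c3', '(9,f8)_s2.c2']
f8.2 paralog ['(8,f8)_s3.c3']
f8.3 singleton ['(6,f8)_s3.c3']
```

Two syntenies `{f2,f8}` and `{f4,f8}` share only the gene at position 9 on
c2 — a weak bond. Because that gene comes from the oldest lineage present on
the smaller side, the larger witness is read as orthologous; family `f8` is
split into three orthologous copies, one paralogous copy (position 8 on c3,
stripped of the bond gene's support), and one unplaced singleton.

The same pipeline is available from the shell:

```sh
syns detect --genes genes.tsv --species-order species.txt --delta 7 --out out/
syns simulate --seed 1 --clusters 4 --out sim/      # synthetic benchmark data
syns compare groups_a.tsv groups_b.tsv              # split/merge accounting
syns oracle --genes genes.tsv --delta 3             # brute-force cross-check
```

`detect` writes `zones.tsv` (one row per witness gene per zone) and
`partition.tsv` (family → subgroup assignments). The gene table format is
TSV with columns `species chromosome gene_id position family` (`*` for
unassigned); the species-order file lists one species per line, most
recently diverged first. δ defaults to 7.

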