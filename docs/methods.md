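# Methods

## Model and procedure

`synteams` works on a purely positional genome model. A chromosome is an
ordered gene sequence; each gene carries a 1-based integer position (its
rank along the chromosome) and either a homologous-family label or the
unassigned marker `*`. Unassigned genes occupy positions and therefore count
toward the distance Δ(g_i, g_j) = |p_i − p_j|, but never enter a
chromosome's family alphabet. Real-coordinate input (GFF3) is reduced to
ranks by sorting features on (sequence id, start); strand is discarded —
nothing in the model uses order within a segment or orientation.
Chromosomes are treated as linear; circular topologies are unsupported.

The pipeline, for a window parameter δ:

1. **δ-subsets.** Per chromosome, every family set of size ≥ 2 induced by at
   least one gene set of span < δ, together with all witnessing segments.
   Witnessing segments need not be contiguous — contiguity is only required
   of the sliding windows used to scan a focal gene's ±δ neighborhood, which
   are a scanning device, not part of cluster identity. "Non-trivial"
   means family set of size ≥ 2 throughout; singleton sets are never
   reported.
2. **δ-clusters.** Family sets that are δ-subsets on ≥ 2 chromosomes; the
   cluster's witness is the union of all genes of all witnessing segments on
   all covering chromosomes. When the scan is restricted to a focal family
   f, only family sets containing f are kept: any witnessing segment for
   such a set contains an f gene and hence automatically lies within ±δ of
   an f member (paralogous copies included), so the neighborhood restriction
   and the membership restriction coincide.
3. **δ-syntenies.** Maximal clusters. A cluster is absorbed into another
   whose family set strictly contains its own and whose witness contains
   every one of its witness genes. The coverage test is monotone, so
   absorption is confluent; clusters are processed in decreasing
   family-set-size order (ties lexicographic) purely to make provenance
   (`merged_from`) deterministic.
4. **δ-zones.** Connected components of the graph joining syntenies whose
   witnesses share ≥ 2 genes. Pairs in different components sharing exactly
   one gene are *weak bonds*.
5. **Weak-bond resolution.** Witnesses are compared by size (ties broken by
   chromosomes covered, then lexicographic family set). With S_i the larger
   witness and g the shared gene: if g's species is ≺-maximal among the
   species present in the smaller witness S_j (equivalently, no witness
   from an older lineage exists on that side), the topology is plausible;
   otherwise it is not. In both cases S_i keeps the orthologous reading and
   S_j \ {g} is kept as a paralogous synteny — the two sides are never
   agglomerated across the bond; the resolution record distinguishes the
   plausible from the implausible case. A zone whose members all end up
   paralogous is a paralogous zone.
6. **Family refinement.** Per family: the orthologous zone with the most
   witness genes of that family (ties: total witness size, then
   lexicographic family set) contributes the orthologous subgroup; every
   paralogous zone whose witness is disjoint from it contributes a
   paralogous subgroup; remaining members become singletons. Subgroups of
   one family are pairwise disjoint by construction.

## Parameters

- **δ (window size), default 7.** The only substantive tuning knob: the
  maximum positional span (exclusive) of a witnessing segment. Smaller δ
  gives finer, more conservative clusters; the set of δ-subsets grows
  monotonically with δ. The default matches the value used for the
  published five-yeast evaluation of this method; any δ ≥ 1 can be passed.
- **Species order.** A total order over species by relative speciation time,
  listed most recently diverged first. It is consulted only for weak-bond
  resolution; runs without weak bonds do not need it. Deriving it from a
  tree is out of scope — it is a plain input file.

## Synthetic generator

`validation_fixtures.generate` emulates the positional structure the
algorithm consumes, nothing more: background positions carry unique
singleton families (which can never witness a cross-chromosome cluster) or
`*`; planted clusters are family sets placed, in per-species shuffled order,
with per-adjacency internal gaps drawn from [0, max_internal_gap];
per-gene loss and tandem paralog duplication are optional. Planted runs on
one chromosome are separated by at least `cluster_spacing` (default 10)
background positions so distinct clusters cannot bridge. Defaults —
5 species, 2 chromosomes/species, 40 background genes/chromosome — are a
deliberately small stand-in for a real multi-genome study; recovery tests
use 4 species, 3 planted clusters of 3 families with gaps ≤ 1, so each
planted run's total span (< 7) is below the default δ and the planted
family set is itself a δ-subset on every carrier chromosome.

What the generator does **not** emulate: realistic rearrangement processes,
rate heterogeneity, gene fission/fusion, shared background families, or
family sizes and chromosome counts at database scale. Passing recovery
therefore shows the pipeline's correctness on clean positional signal, not
its behaviour on noisy real annotations.

## Numerical and degenerate-input choices

- δ-segment test by span (max − min position < δ), provably equal to the
  all-pairs distance condition; a property test asserts the equivalence.
- δ = 1 yields single-gene windows and no non-trivial subsets; a single
  chromosome yields no clusters (two-chromosome minimum) and an
  all-singleton partition.
- All emitted collections are canonically sorted (family sets
  lexicographically, genes by id), so outputs are byte-identical across
  runs and invariant under permutation of input chromosome order.
- Weak bonds arising between syntenies already inside one zone are ignored
  (they are transitively connected through stronger overlaps); a synteny on
  the smaller side of several bonds loses every bond gene.
- Cluster enumeration anchors each δ-segment at its lowest-position gene, so
  each segment is generated exactly once; per-anchor work is bounded by
  2^(δ−1), fine for the intended δ ≤ ~10.

## Validation design

The brute-force oracle re-derives syntenies by literal exhaustive
enumeration (all gene combinations inside every width-δ position window,
pairwise maximality checks in increasing-size order) — a deliberately
different traversal from the production path, so a shared bug cannot cancel.
The six worked examples of the method's original description are encoded as
fixtures with their printed expected outputs; two of them print slightly
different positions for the same chromosomes, so each example carries its
own variant and is validated in isolation. One printed witness list omits a
gene that its own stated positions place within δ of a witness; the fixture
expectation includes it (the downstream zone result is unchanged).

## Classification comparison

`classification_compare` restricts both classifications to their common
gene universe and classifies each connected component of the bipartite
group-overlap graph as identical (1-to-1, equal member sets), split (one
group vs ≥ 2), merge (the symmetric case) or messy (anything larger).
The similarity value is the mean per-gene Jaccard index between the gene's
two groups on the common universe — a substitute for the externally defined
similarity of the original report, and labelled as such in every emitted
summary. "Singletons" counts genes grouped alone by the second
classification while covered by the first; the report legend states this.

## Known limitations

- Complexity is exponential in the number of genes inside one δ window;
  pathological inputs (hundreds of genes at consecutive positions with many
  distinct families within one window) will be slow. Real gene orders with
  δ ≤ 10 are unproblematic.
- Weak-bond resolution uses witness size as a proxy for evidence strength;
  equal-size witnesses are ordered by a documented deterministic tie-break,
  not by biological criteria.
- The family partition covers only witness genes; family members outside
  any conserved neighborhood are reported as singletons rather than being
  assigned by any similarity fallback — families are input here, never
  inferred.
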