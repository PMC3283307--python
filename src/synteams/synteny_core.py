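"""δ-subsets, δ-clusters and maximal δ-syntenies.

The hierarchy, bottom up:

* a *δ-segment* is a gene set on one chromosome in which every pair of genes
  is closer than δ positions;
* a family set Σ′ is a *δ-subset* of a chromosome if at least one δ-segment
  induces exactly Σ′ — every such segment is a *witness*;
* Σ′ is a *δ-cluster* if it is a δ-subset on at least two chromosomes; its
  witness is the union of all genes participating in witnessing segments;
* a *δ-synteny* is a maximal δ-cluster: a cluster is absorbed into another
  whose family set strictly contains it and whose witness covers every one of
  its witness genes.

Windows (contiguous δ-segments) are the scanning device of the sliding-window
algorithm; witnessing segments themselves need not be contiguous.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

from .genome_model import Chromosome, Gene, GenomeSet, Segment

__all__ = [
    "Window",
    "DeltaSubset",
    "DeltaCluster",
    "Synteny",
    "neighborhood_windows",
    "delta_subsets",
    "delta_clusters",
    "all_delta_clusters",
    "maximal_syntenies",
]


@dataclass(frozen=True)
class Window:
    """A contiguous δ-segment scanned around a focal family member."""

    segment: Segment
    focal_gene: Gene
    start: int
    end: int


@dataclass(frozen=True)
class DeltaSubset:
    """A family set witnessed on one chromosome, with all its witnesses."""

    families: frozenset[str]
    chromosome_key: tuple[str, str]
    witnesses: frozenset[frozenset[Gene]]

    @property
    def witness_genes(self) -> frozenset[Gene]:
        return frozenset(g for w in self.witnesses for g in w)


@dataclass(frozen=True)
class DeltaCluster:
    """A family set that is a δ-subset on at least two chromosomes."""

    families: frozenset[str]
    witness: frozenset[Gene]
    chromosome_cover: frozenset[tuple[str, str]]

    def witness_on(self, chromosome_key: tuple[str, str]) -> frozenset[Gene]:
        return frozenset(g for g in self.witness if g.chromosome_key == chromosome_key)

    def sort_key(self):
        return (tuple(sorted(self.families)), tuple(sorted(self.chromosome_cover)))


@dataclass(frozen=True)
class Synteny(DeltaCluster):
    """A maximal δ-cluster, with the absorbed smaller clusters as provenance."""

    merged_from: tuple[DeltaCluster, ...] = field(default=(), compare=False)


def neighborhood_windows(
    chromosome: Chromosome, focal: Gene, delta: int
) -> tuple[Window, ...]:
    """All maximal windows of width δ inside the ±δ neighborhood of ``focal``.

    Each window is a run of δ consecutive positions clipped to the
    neighborhood ``[p_focal − δ, p_focal + δ]`` and to the chromosome; its
    segment holds the assigned genes it contains. Windows are maximal by
    position range: every contiguous δ-segment of the neighborhood is a
    subset of one of them.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if chromosome.gene_at(focal.position) != focal:
        raise ValueError(f"focal gene {focal.gene_id} is not on {chromosome.key}")
    top = chromosome.genes[-1].position
    lo = max(1, focal.position - delta)
    hi = min(top, focal.position + delta)
    windows: list[Window] = []
    if hi - lo + 1 <= delta:
        starts = [lo]
    else:
        starts = list(range(lo, hi - delta + 2))
    for s in starts:
        e = min(s + delta - 1, hi)
        genes = frozenset(
            g
            for g in chromosome.genes
            if s <= g.position <= e and g.is_assigned
        )
        if not genes:
            continue
        windows.append(
            Window(
                segment=Segment(genes=genes, chromosome=chromosome),
                focal_gene=focal,
                start=s,
                end=e,
            )
        )
    return tuple(windows)


@functools.lru_cache(maxsize=4096)
def delta_subsets(chromosome: Chromosome, delta: int) -> tuple[DeltaSubset, ...]:
    """All non-trivial (|Σ′| ≥ 2) δ-subsets of a chromosome with complete
    witness lists.

    Enumerates every δ-segment of assigned genes exactly once by anchoring on
    its lowest-position gene; a witness may be non-contiguous.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    assigned = chromosome.assigned_genes
    found: dict[frozenset[str], set[frozenset[Gene]]] = {}
    for i, anchor in enumerate(assigned):
        pool = [
            g
            for g in assigned[i + 1 :]
            if g.position <= anchor.position + delta - 1
        ]
        for r in range(1, len(pool) + 1):
            for combo in itertools.combinations(pool, r):
                seg = frozenset((anchor, *combo))
                fams = frozenset(g.family for g in seg)
                if len(fams) >= 2:
                    found.setdefault(fams, set()).add(seg)
    return tuple(
        DeltaSubset(
            families=fams,
            chromosome_key=chromosome.key,
            witnesses=frozenset(segs),
        )
        for fams, segs in sorted(found.items(), key=lambda kv: sorted(kv[0]))
    )


def _cluster_index(
    genomes: GenomeSet, delta: int
) -> dict[frozenset[str], dict[tuple[str, str], frozenset[Gene]]]:
    """family set -> chromosome -> union of witness genes on that chromosome."""
    index: dict[frozenset[str], dict[tuple[str, str], frozenset[Gene]]] = {}
    for c in genomes.chromosomes:
        for ds in delta_subsets(c, delta):
            index.setdefault(ds.families, {})[c.key] = ds.witness_genes
    return index


def all_delta_clusters(genomes: GenomeSet, delta: int) -> tuple[DeltaCluster, ...]:
    """Every non-trivial δ-cluster of the genome set (all families)."""
    clusters = []
    for fams, per_chrom in _cluster_index(genomes, delta).items():
        if len(per_chrom) >= 2:
            witness = frozenset(g for gs in per_chrom.values() for g in gs)
            clusters.append(
                DeltaCluster(
                    families=fams,
                    witness=witness,
                    chromosome_cover=frozenset(per_chrom),
                )
            )
    return tuple(sorted(clusters, key=DeltaCluster.sort_key))


def delta_clusters(
    genomes: GenomeSet, delta: int, focal_family: str
) -> tuple[DeltaCluster, ...]:
    """δ-clusters found in the neighborhoods of ``focal_family`` members.

    A witnessing segment for a family set containing the focal family always
    contains a focal-family gene (paralogous copies included), so it lies
    within ±δ of a member; the neighborhood restriction is therefore exactly
    the restriction to family sets containing the focal family.
    """
    if focal_family not in genomes.families:
        raise KeyError(f"unknown family: {focal_family}")
    return tuple(
        c for c in all_delta_clusters(genomes, delta) if focal_family in c.families
    )


def maximal_syntenies(clusters: tuple[DeltaCluster, ...] | list[DeltaCluster] | set) -> tuple[Synteny, ...]:
    """Merge δ-clusters into maximal δ-syntenies.

    Cluster Σ′ is absorbed into Σ iff families(Σ′) ⊊ families(Σ) and every
    witness gene of Σ′ belongs to Σ's witness. Absorption is confluent (the
    coverage test is monotone), so the processing order — decreasing family
    set size, ties lexicographic — only fixes provenance attribution.
    """
    ordered = sorted(
        clusters, key=lambda c: (-len(c.families), tuple(sorted(c.families)))
    )
    absorbed_by: dict[int, int] = {}
    for i, small in enumerate(ordered):
        for j, big in enumerate(ordered):
            if i == j:
                continue
            if small.families < big.families and small.witness <= big.witness:
                absorbed_by[i] = j
                break  # ordered scan: first hit is the largest absorber
    def survivor_of(i: int) -> int:
        while i in absorbed_by:
            i = absorbed_by[i]
        return i

    out = []
    for j, c in enumerate(ordered):
        if j in absorbed_by:
            continue
        merged = tuple(
            ordered[i] for i in sorted(absorbed_by) if survivor_of(i) == j
        )
        out.append(
            Synteny(
                families=c.families,
                witness=c.witness,
                chromosome_cover=c.chromosome_cover,
                merged_from=merged,
            )
        )
    return tuple(sorted(out, key=DeltaCluster.sort_key))
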