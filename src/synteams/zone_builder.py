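"""δ-zones, weak bonds, phylogeny-ordered resolution, and the SYNS driver.

Syntenies whose witnesses share at least two genes are transitively
agglomerated into *δ-zones*. A pair sharing exactly one gene forms a *weak
bond*: a single shared (typically paralogous) gene is too little evidence to
fuse neighborhoods, so the bond is resolved against the species divergence
order ≺ ("a ≺ b" when b diverged from the common ancestor earlier). The
larger witness keeps the orthologous reading; the smaller one loses the bond
gene and is kept as a paralogous synteny. When the bond gene's species is
not maximal among the smaller witness's species — i.e. an older lineage is
present on that side — the topology is evolutionarily implausible and no
agglomeration across the bond is ever accepted.

The driver scans every family (paralogous copies included), builds clusters,
merges them into syntenies, agglomerates zones, resolves weak bonds, and
refines each input family into orthologous / paralogous / singleton
subgroups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .genome_model import Gene, GenomeSet
from .synteny_core import (
    DeltaCluster,
    Synteny,
    all_delta_clusters,
    delta_clusters,
    maximal_syntenies,
)

__all__ = [
    "ORTHOLOGOUS",
    "PARALOGOUS",
    "DEFAULT_DELTA",
    "SpeciesOrder",
    "WeakBond",
    "WeakBondResolution",
    "Zone",
    "Subgroup",
    "FamilyPartition",
    "SynsResult",
    "agglomerate_zones",
    "resolve_weak_bond",
    "finalize_partition",
    "syns_run",
]

ORTHOLOGOUS = "orthologous"
PARALOGOUS = "paralogous"

#: Default window size; the value used for the published evaluation.
DEFAULT_DELTA = 7


@dataclass(frozen=True)
class SpeciesOrder:
    """Total order ≺ over species, listed from ≺-smallest (most recently
    diverged) to ≺-biggest (earliest diverged)."""

    sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.sequence)) != len(self.sequence):
            raise ValueError("species order contains duplicates")

    def rank(self, species: str) -> int:
        try:
            return self.sequence.index(species)
        except ValueError:
            raise KeyError(f"species not in order: {species}") from None

    def biggest(self, species: Iterable[str]) -> str:
        """The earliest-diverged species among ``species``."""
        sp = list(species)
        if not sp:
            raise ValueError("empty species set")
        return max(sp, key=self.rank)


@dataclass(frozen=True)
class WeakBond:
    """Two syntenies sharing exactly one witness gene."""

    synteny_i: Synteny
    synteny_j: Synteny
    witness_gene: Gene


@dataclass(frozen=True)
class WeakBondResolution:
    """Outcome of resolving a weak bond against the species order.

    ``plausible`` distinguishes the two evolutionarily acceptable topologies
    (bond gene in the oldest lineage present on the smaller side, or no older
    lineage there at all) from the implausible one. In every case the larger
    witness is read as orthologous and the smaller one, stripped of the bond
    gene, as paralogous; an implausible bond additionally vetoes any
    agglomeration across it.
    """

    bond: WeakBond
    plausible: bool
    orthologous: Synteny
    paralogous: Synteny
    removed_gene: Gene


@dataclass(frozen=True)
class Zone:
    """A union of transitively connected syntenies."""

    members: tuple[Synteny, ...]
    label: str = ORTHOLOGOUS
    stripped: frozenset[Gene] = frozenset()

    @property
    def families(self) -> frozenset[str]:
        return frozenset(f for s in self.members for f in s.families)

    @property
    def witness(self) -> frozenset[Gene]:
        return frozenset(
            g for s in self.members for g in s.witness
        ) - self.stripped

    def family_witness(self, family: str) -> frozenset[Gene]:
        return frozenset(g for g in self.witness if g.family == family)

    def sort_key(self):
        return (
            tuple(sorted(self.families)),
            tuple(sorted(g.gene_id for g in self.witness)),
        )


@dataclass(frozen=True)
class Subgroup:
    family: str
    kind: str  # "ortholog" | "paralog" | "singleton"
    genes: frozenset[Gene]
    subgroup_id: str = field(default="", compare=False)


class FamilyPartition:
    """Refinement of input families into ortholog/paralog/singleton subgroups."""

    def __init__(self, subgroups: Iterable[Subgroup]) -> None:
        self.by_family: dict[str, tuple[Subgroup, ...]] = {}
        staging: dict[str, list[Subgroup]] = {}
        for sg in subgroups:
            staging.setdefault(sg.family, []).append(sg)
        for fam in sorted(staging):
            ordered = sorted(
                staging[fam],
                key=lambda s: (
                    {"ortholog": 0, "paralog": 1, "singleton": 2}[s.kind],
                    tuple(sorted(g.gene_id for g in s.genes)),
                ),
            )
            named = []
            for i, sg in enumerate(ordered, start=1):
                named.append(
                    Subgroup(
                        family=sg.family,
                        kind=sg.kind,
                        genes=sg.genes,
                        subgroup_id=f"{fam}.{i}",
                    )
                )
                covered = set()
                for other in named[:-1]:
                    covered |= other.genes
                if covered & sg.genes:
                    raise ValueError(
                        f"subgroups of family {fam} are not pairwise disjoint"
                    )
            self.by_family[fam] = tuple(named)

    def subgroups(self) -> Iterable[Subgroup]:
        for fam in self.by_family:
            yield from self.by_family[fam]

    def __getitem__(self, family: str) -> tuple[Subgroup, ...]:
        return self.by_family[family]

    def __repr__(self) -> str:
        n = sum(len(v) for v in self.by_family.values())
        return f"FamilyPartition({len(self.by_family)} families, {n} subgroups)"


@dataclass(frozen=True)
class SynsResult:
    zones: tuple[Zone, ...]
    partition: FamilyPartition
    syntenies: tuple[Synteny, ...]
    weak_bonds: tuple[WeakBond, ...]
    resolutions: tuple[WeakBondResolution, ...]

    @property
    def nontrivial_zones(self) -> tuple[Zone, ...]:
        return tuple(z for z in self.zones if len(z.families) >= 2)


def agglomerate_zones(
    syntenies: Iterable[Synteny],
) -> tuple[tuple[Zone, ...], tuple[WeakBond, ...]]:
    """Transitive agglomeration: connected components of the graph whose
    edges join syntenies with witness intersection of size ≥ 2.

    Pairs in *different* components sharing exactly one witness gene are
    returned as weak bonds for phylogeny-ordered resolution; pairs inside one
    component are already transitively connected and need none.
    """
    syntenies = tuple(sorted(syntenies, key=DeltaCluster.sort_key))
    graph = nx.Graph()
    graph.add_nodes_from(range(len(syntenies)))
    for i, j in itertools.combinations(range(len(syntenies)), 2):
        if len(syntenies[i].witness & syntenies[j].witness) >= 2:
            graph.add_edge(i, j)
    component_of: dict[int, int] = {}
    zones = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted((syntenies[i] for i in comp), key=DeltaCluster.sort_key))
        zones.append(Zone(members=members))
        for i in comp:
            component_of[i] = len(zones) - 1
    bonds = []
    for i, j in itertools.combinations(range(len(syntenies)), 2):
        if component_of[i] == component_of[j]:
            continue
        shared = syntenies[i].witness & syntenies[j].witness
        if len(shared) == 1:
            bonds.append(
                WeakBond(
                    synteny_i=syntenies[i],
                    synteny_j=syntenies[j],
                    witness_gene=next(iter(shared)),
                )
            )
    return tuple(sorted(zones, key=Zone.sort_key)), tuple(bonds)


def _bigger_smaller(bond: WeakBond) -> tuple[Synteny, Synteny]:
    """Order the bonded pair so the first element carries the larger witness;
    ties broken by chromosome cover then lexicographic family set."""

    def key(s: Synteny):
        return (
            len(s.witness),
            len(s.chromosome_cover),
            tuple(sorted(s.families, reverse=True)),
        )

    a, b = bond.synteny_i, bond.synteny_j
    return (a, b) if key(a) >= key(b) else (b, a)


def resolve_weak_bond(bond: WeakBond, order: SpeciesOrder) -> WeakBondResolution:
    """Split a weak bond into an orthologous and a paralogous synteny.

    Let S_i be the larger witness and g the single shared gene. If g comes
    from the ≺-biggest species present in the smaller witness S_j (or no
    ≺-bigger species is present there), the topology is plausible; otherwise
    it is not. Either way S_i witnesses the maximal orthologous synteny and
    S_j \\ {g} a paralogous one.
    """
    shared = bond.synteny_i.witness & bond.synteny_j.witness
    if len(shared) != 1:
        raise ValueError(
            f"not a weak bond: witness intersection has size {len(shared)}"
        )
    big, small = _bigger_smaller(bond)
    g = bond.witness_gene
    species_j = {w.species for w in small.witness}
    plausible = order.rank(g.species) >= max(order.rank(sp) for sp in species_j)
    stripped = small.witness - {g}
    paralogous = Synteny(
        families=small.families,
        witness=stripped,
        chromosome_cover=frozenset(w.chromosome_key for w in stripped),
        merged_from=small.merged_from,
    )
    return WeakBondResolution(
        bond=bond,
        plausible=plausible,
        orthologous=big,
        paralogous=paralogous,
        removed_gene=g,
    )


def _apply_resolutions(
    zones: tuple[Zone, ...], resolutions: Sequence[WeakBondResolution]
) -> tuple[Zone, ...]:
    """Relabel zones after weak-bond resolution.

    A synteny that ends up on the paralogous side of some bond loses the bond
    gene; a zone all of whose members are paralogous is a paralogous zone.
    """
    para_syntenies: dict[Synteny, set[Gene]] = {}
    for res in resolutions:
        _, small = _bigger_smaller(res.bond)
        para_syntenies.setdefault(small, set()).add(res.removed_gene)
    out = []
    for z in zones:
        removed = set()
        n_para = 0
        for m in z.members:
            if m in para_syntenies:
                n_para += 1
                removed |= para_syntenies[m]
        label = PARALOGOUS if n_para == len(z.members) else ORTHOLOGOUS
        out.append(
            Zone(members=z.members, label=label, stripped=frozenset(removed))
        )
    return tuple(sorted(out, key=Zone.sort_key))


def finalize_partition(zones: Iterable[Zone], genomes: GenomeSet) -> FamilyPartition:
    """Refine every family: keep its largest orthologous zone and the
    paralogous zones disjoint from it; everything else becomes singletons.

    "Largest" counts witness genes of the family in question, with total
    witness size then lexicographic family set as tie-breaks.
    """
    zones = tuple(zones)
    subgroups: list[Subgroup] = []
    for fam in sorted(genomes.families):
        members = genomes.families[fam]
        ortho = [
            z
            for z in zones
            if z.label == ORTHOLOGOUS and z.family_witness(fam)
        ]
        retained_o = None
        if ortho:
            retained_o = max(
                ortho,
                key=lambda z: (
                    len(z.family_witness(fam)),
                    len(z.witness),
                    tuple(sorted(z.families, reverse=True)),
                ),
            )
        covered: set[Gene] = set()
        if retained_o is not None:
            genes = retained_o.family_witness(fam)
            subgroups.append(Subgroup(family=fam, kind="ortholog", genes=genes))
            covered |= genes
        for z in zones:
            if z.label != PARALOGOUS or not z.family_witness(fam):
                continue
            if retained_o is not None and (z.witness & retained_o.witness):
                continue
            genes = z.family_witness(fam) - covered
            if genes:
                subgroups.append(Subgroup(family=fam, kind="paralog", genes=genes))
                covered |= genes
        for g in sorted(members - covered):
            subgroups.append(
                Subgroup(family=fam, kind="singleton", genes=frozenset({g}))
            )
    return FamilyPartition(subgroups)


def syns_run(
    genomes: GenomeSet,
    delta: int = DEFAULT_DELTA,
    families: Iterable[str] | None = None,
) -> SynsResult:
    """End-to-end SYNS: clusters → syntenies → zones → weak-bond resolution
    → refined family partition.

    ``families`` restricts the scan to the neighborhoods of the given focal
    families (all families by default). The result is deterministic and
    independent of chromosome or family iteration order.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    if families is None:
        clusters = all_delta_clusters(genomes, delta)
    else:
        seen: dict[frozenset[str], DeltaCluster] = {}
        for fam in sorted(set(families)):
            for c in delta_clusters(genomes, delta, fam):
                seen[c.families] = c
        clusters = tuple(sorted(seen.values(), key=DeltaCluster.sort_key))
    syntenies = maximal_syntenies(clusters)
    zones, bonds = agglomerate_zones(syntenies)
    resolutions: tuple[WeakBondResolution, ...] = ()
    if bonds:
        if genomes.species_order is None:
            raise ValueError(
                "weak bonds present but the genome set has no species order"
            )
        resolutions = tuple(
            resolve_weak_bond(b, genomes.species_order) for b in bonds
        )
        zones = _apply_resolutions(zones, resolutions)
    partition = finalize_partition(zones, genomes)
    return SynsResult(
        zones=zones,
        partition=partition,
        syntenies=syntenies,
        weak_bonds=bonds,
        resolutions=resolutions,
    )
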