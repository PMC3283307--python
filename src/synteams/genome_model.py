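"""Positional genome model: species, chromosomes, positioned genes, segments.

A chromosome is an ordered sequence of genes, each gene a pair
``(position, family)``. Positions are 1-based integer ranks; genes that are
not assigned to any homologous family are recorded with the :data:`UNASSIGNED`
sentinel (``*``) — they occupy positions and count toward distances but never
enter a chromosome's family alphabet.

The model is unordered and orientation-free: no downstream definition uses
gene order within a segment or strand, only positional distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "UNASSIGNED",
    "Gene",
    "Chromosome",
    "GenomeSet",
    "Segment",
    "parse_compact_notation",
    "render_compact_notation",
    "distance",
    "induced_families",
    "is_contiguous",
    "is_delta_segment",
]

#: Sentinel family label for genes without a homologous-family assignment.
UNASSIGNED = "*"


@dataclass(frozen=True, order=True)
class Gene:
    """One positioned gene on a chromosome of a species.

    ``family`` is either a family identifier or :data:`UNASSIGNED`.
    """

    species: str
    chromosome: str
    position: int
    family: str
    gene_id: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"gene position must be >= 1, got {self.position}")
        if not self.gene_id:
            object.__setattr__(
                self, "gene_id", f"{self.species}.{self.chromosome}.{self.position}"
            )

    @property
    def is_assigned(self) -> bool:
        return self.family != UNASSIGNED

    @property
    def chromosome_key(self) -> tuple[str, str]:
        return (self.species, self.chromosome)

    def __repr__(self) -> str:  # compact, example-style
        return f"({self.position},{self.family})_{self.species}.{self.chromosome}"


@dataclass(frozen=True)
class Chromosome:
    """An ordered gene sequence together with its family alphabet."""

    species: str
    chromosome_id: str
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        positions = [g.position for g in self.genes]
        if any(q <= p for p, q in zip(positions, positions[1:])):
            raise ValueError(
                f"positions must be strictly increasing on "
                f"{self.species}/{self.chromosome_id}"
            )
        for g in self.genes:
            if g.chromosome_key != self.key:
                raise ValueError(
                    f"gene {g.gene_id} does not belong to chromosome "
                    f"{self.species}/{self.chromosome_id}"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.chromosome_id)

    @property
    def alphabet(self) -> frozenset[str]:
        """The set of family labels occurring on this chromosome (no ``*``)."""
        return frozenset(g.family for g in self.genes if g.is_assigned)

    @property
    def assigned_genes(self) -> tuple[Gene, ...]:
        return tuple(g for g in self.genes if g.is_assigned)

    def gene_at(self, position: int) -> Gene | None:
        return self._by_position().get(position)

    def _by_position(self) -> dict[int, Gene]:
        # frozen dataclass: cache via object.__setattr__
        cached = self.__dict__.get("_pos_index")
        if cached is None:
            cached = {g.position: g for g in self.genes}
            object.__setattr__(self, "_pos_index", cached)
        return cached

    def __len__(self) -> int:
        return len(self.genes)

    def __hash__(self) -> int:
        return hash((self.species, self.chromosome_id, self.genes))


@dataclass(frozen=True)
class Segment:
    """A non-empty gene set from one chromosome (a chromosomal segment)."""

    genes: frozenset[Gene]
    chromosome: Chromosome

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a segment must contain at least one gene")
        keys = {g.chromosome_key for g in self.genes}
        if keys != {self.chromosome.key}:
            raise ValueError("all segment genes must share one (species, chromosome)")

    @property
    def families(self) -> frozenset[str]:
        return induced_families(self.genes)

    @property
    def span(self) -> int:
        positions = [g.position for g in self.genes]
        return max(positions) - min(positions)


class GenomeSet:
    """A collection of chromosomes across species plus the family table."""

    def __init__(
        self,
        chromosomes: Iterable[Chromosome],
        species_order=None,
        family_table: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        self.chromosomes: tuple[Chromosome, ...] = tuple(
            sorted(chromosomes, key=lambda c: c.key)
        )
        seen: set[tuple[str, str]] = set()
        for c in self.chromosomes:
            if c.key in seen:
                raise ValueError(f"duplicate chromosome {c.key}")
            seen.add(c.key)
        self.species_order = species_order
        self.families: dict[str, frozenset[Gene]] = {}
        by_family: dict[str, set[Gene]] = {}
        for c in self.chromosomes:
            for g in c.genes:
                if g.is_assigned:
                    by_family.setdefault(g.family, set()).add(g)
        self.families = {f: frozenset(gs) for f, gs in by_family.items()}
        if family_table is not None:
            known = set(family_table)
            unknown = sorted(set(self.families) - known)
            if unknown:
                raise ValueError(
                    f"gene table references families absent from the family "
                    f"table: {', '.join(unknown)}"
                )
        if species_order is not None:
            missing = self.species - set(species_order.sequence)
            if missing:
                raise ValueError(
                    f"species order does not cover species: {sorted(missing)}"
                )

    @property
    def species(self) -> set[str]:
        return {c.species for c in self.chromosomes}

    def chromosome(self, species: str, chromosome_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.key == (species, chromosome_id):
                return c
        raise KeyError((species, chromosome_id))

    def genes(self) -> Iterable[Gene]:
        for c in self.chromosomes:
            yield from c.genes

    def __repr__(self) -> str:
        return (
            f"GenomeSet({len(self.chromosomes)} chromosomes, "
            f"{len(self.families)} families)"
        )


def parse_compact_notation(text: str, species_id: str, chromosome_id: str) -> Chromosome:
    """Build a chromosome from an angle-bracket family string.

    Whitespace-separated tokens; ``*`` marks an unassigned gene. Token *k*
    (1-based) becomes the gene at position *k*, so asterisks occupy positions
    and count toward distances without joining the alphabet.

    >>> c = parse_compact_notation("f2 f1 * f4 * * * f3 f1", "s1", "c1")
    >>> [(g.position, g.family) for g in c.assigned_genes]
    [(1, 'f2'), (2, 'f1'), (4, 'f4'), (7, 'f3'), (8, 'f1')]
    """
    tokens = text.split()
    if not tokens:
        raise ValueError("empty compact-notation string")
    genes = tuple(
        Gene(species=species_id, chromosome=chromosome_id, position=k, family=tok)
        for k, tok in enumerate(tokens, start=1)
    )
    return Chromosome(species=species_id, chromosome_id=chromosome_id, genes=genes)


def render_compact_notation(chromosome: Chromosome) -> str:
    """Inverse of :func:`parse_compact_notation`; position gaps render as ``*``."""
    if not chromosome.genes:
        return ""
    top = chromosome.genes[-1].position
    tokens = []
    for p in range(1, top + 1):
        g = chromosome.gene_at(p)
        tokens.append(g.family if g is not None else UNASSIGNED)
    return " ".join(tokens)


def distance(g_i: Gene, g_j: Gene) -> int:
    """Positional distance Δ(g_i, g_j) = |p_i − p_j| on one chromosome."""
    if g_i.chromosome_key != g_j.chromosome_key:
        raise ValueError(
            f"distance undefined across chromosomes: "
            f"{g_i.chromosome_key} vs {g_j.chromosome_key}"
        )
    return abs(g_i.position - g_j.position)


def induced_families(genes: Iterable[Gene]) -> frozenset[str]:
    """The family set Σ(G′) induced by a gene set; unassigned genes excluded."""
    return frozenset(g.family for g in genes if g.is_assigned)


def is_contiguous(segment: Segment) -> bool:
    """True iff every position strictly between two member positions holds a
    member gene or an unassigned gene."""
    positions = sorted(g.position for g in segment.genes)
    members = set(positions)
    for p in range(positions[0] + 1, positions[-1]):
        if p in members:
            continue
        g = segment.chromosome.gene_at(p)
        if g is not None and g.is_assigned:
            return False
    return True


def is_delta_segment(segment: Segment, delta: int) -> bool:
    """True iff every gene pair is separated by a distance smaller than δ.

    Equivalent to ``max position − min position < delta``.
    """
    if delta < 1:
        raise ValueError("delta must be >= 1")
    return segment.span < delta
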