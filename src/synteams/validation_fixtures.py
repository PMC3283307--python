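"""Executable worked-example fixtures, an independent brute-force oracle,
and a synthetic genome generator with planted clusters.

The six worked examples are encoded from their printed gene positions and
expected outputs. Two of them describe the same three chromosomes at
slightly different printed positions (an internal inconsistency of the
source figures), so each example carries its own chromosome variant and is
validated in isolation.

The brute-force oracle re-derives δ-subsets, δ-clusters and δ-syntenies by
literal exhaustive enumeration with a different traversal than the
production path, so shared bugs cannot cancel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    UNASSIGNED,
    Chromosome,
    Gene,
    GenomeSet,
    parse_compact_notation,
)
from .synteny_core import DeltaCluster, Synteny
from .zone_builder import SpeciesOrder

__all__ = [
    "WorkedExample",
    "SyntheticSpec",
    "PlantedCluster",
    "GroundTruth",
    "load_example",
    "brute_force_syntenies",
    "brute_force_subsets",
    "generate",
    "random_genome_set",
]

# ---------------------------------------------------------------------------
# Worked-example fixtures


@dataclass(frozen=True)
class WorkedExample:
    """One worked example: chromosomes in compact notation plus the expected
    printed outputs, keyed by stage name."""

    example_id: int
    chromosomes: dict[str, str]  # chromosome id -> compact string
    delta: int
    species_order: tuple[str, ...] | None
    expected: dict

    def genome_set(self) -> GenomeSet:
        chroms = [
            parse_compact_notation(text, species_id=f"s{cid[1:]}", chromosome_id=cid)
            for cid, text in self.chromosomes.items()
        ]
        order = (
            SpeciesOrder(self.species_order) if self.species_order else None
        )
        return GenomeSet(chroms, species_order=order)

    def gene(self, chromosome_id: str, position: int) -> Gene:
        gs = self.genome_set()
        return gs.chromosome(f"s{chromosome_id[1:]}", chromosome_id).gene_at(position)


def _fs(*items: str) -> frozenset[str]:
    return frozenset(items)


_EXAMPLES: dict[int, WorkedExample] = {}

_EXAMPLES[1] = WorkedExample(
    example_id=1,
    chromosomes={
        "c1": "f2 f1 * f4 * * f3 f1",
        "c2": "f1 f2 f2 f3 * f4",
    },
    delta=3,
    species_order=None,
    expected={
        "c1_genes": [(1, "f2"), (2, "f1"), (4, "f4"), (7, "f3"), (8, "f1")],
        "c1_unassigned_positions": [3, 5, 6],
        "c2_genes": [(1, "f1"), (2, "f2"), (3, "f2"), (4, "f3"), (6, "f4")],
        "alphabet": {"f1", "f2", "f3", "f4"},
        # the worked non-contiguous / contiguous segments on c1
        "noncontiguous_segment_positions": [2, 4, 8],
        "contiguous_segment_positions": [4, 7, 8],
    },
)

_EXAMPLES[2] = WorkedExample(
    example_id=2,
    chromosomes={"c2": "f1 f2 f2 f3 * f4"},
    delta=3,
    species_order=None,
    expected={
        # family set -> list of witnesses, each a tuple of positions
        "subsets": {
            _fs("f1", "f2"): {(1, 2), (1, 3), (1, 2, 3)},
            _fs("f2", "f3"): {(2, 4), (3, 4), (2, 3, 4)},
            _fs("f3", "f4"): {(4, 6)},
        }
    },
)

# Asterisk runs reconstructed so that the printed cluster/synteny lists hold.
_EXAMPLES[3] = WorkedExample(
    example_id=3,
    chromosomes={
        "c1": "f3 * * f5 f4 f1 * f2 * * f5 f4",
        "c2": "f1 f2 * * f3 * * f4 f5 f1 * f5",
        "c3": "f2 * f3 * * * f5 * f1 f4 * f5",
    },
    delta=3,
    species_order=None,
    expected={
        # printed per-pair cluster lists (each family set must cover the pair)
        "cluster_pairs": {
            ("c1", "c2"): {
                _fs("f4", "f1"),
                _fs("f5", "f1"),
                _fs("f4", "f5", "f1"),
                _fs("f1", "f2"),
                _fs("f4", "f5"),
            },
            ("c1", "c3"): {_fs("f1", "f5"), _fs("f1", "f4"), _fs("f4", "f5")},
        },
        "cluster_family_sets": {
            _fs("f4", "f1"),
            _fs("f5", "f1"),
            _fs("f4", "f5", "f1"),
            _fs("f1", "f2"),
            _fs("f4", "f5"),
        },
        "syntenies": {
            _fs("f4", "f5"),
            _fs("f1", "f2"),
            _fs("f4", "f1"),
            _fs("f5", "f1"),
            _fs("f4", "f5", "f1"),
        },
        "focal_f1_family_sets": {
            _fs("f4", "f1"),
            _fs("f5", "f1"),
            _fs("f4", "f5", "f1"),
            _fs("f1", "f2"),
        },
    },
)

_EXAMPLES[4] = WorkedExample(
    example_id=4,
    chromosomes={
        "c1": "f1 * * f4 * f6 f6 f7 f8 f9",
        "c2": "* f5 * * f3 f6 f2 f4 f8 f7 f9",
        "c3": "f4 f8 f4 * f7 f8 f8 * f8 f2",
    },
    delta=3,
    species_order=None,
    expected={
        "focal": "f8",
        "cluster_pairs": {
            ("c1", "c2"): {
                _fs("f7", "f8", "f9"),
                _fs("f7", "f8"),
                _fs("f8", "f9"),
            },
            ("c1", "c3"): {_fs("f7", "f8")},
            ("c2", "c3"): {_fs("f8", "f2"), _fs("f7", "f8"), _fs("f8", "f4")},
        },
        "cluster_family_sets": {
            _fs("f7", "f8", "f9"),
            _fs("f7", "f8"),
            _fs("f8", "f9"),
            _fs("f8", "f2"),
            _fs("f8", "f4"),
        },
        "syntenies": {
            _fs("f7", "f8", "f9"),
            _fs("f7", "f8"),
            _fs("f8", "f2"),
            _fs("f8", "f4"),
        },
        "absorbed": {_fs("f8", "f9"): _fs("f7", "f8", "f9")},
    },
)

_EXAMPLES[5] = WorkedExample(
    example_id=5,
    chromosomes={
        "c1": "f1 * * f4 * f6 f6 f7 f8",
        "c2": "* f5 * * f3 f6 * f4 f8 f7",
        "c3": "f4 f8 f4 f7 f8 f8 * f8 f2",
    },
    delta=3,
    species_order=None,
    expected={
        "focal": "f8",
        # the two printed syntenies, witnesses as (chromosome, position) pairs
        "synteny_witnesses": {
            _fs("f7", "f8"): {
                ("c1", 8),
                ("c1", 9),
                ("c2", 9),
                ("c2", 10),
                ("c3", 2),
                ("c3", 4),
                ("c3", 5),
                ("c3", 6),
            },
            _fs("f4", "f8"): {
                ("c2", 8),
                ("c2", 9),
                ("c3", 1),
                ("c3", 2),
                ("c3", 3),
                ("c3", 5),
            },
        },
        "zone_families": _fs("f4", "f8", "f7"),
        "excluded_gene": ("c3", 8),
    },
)

_EXAMPLES[6] = WorkedExample(
    example_id=6,
    chromosomes={
        "c2": "* f5 * * f3 f6 f4 f2 f8",
        "c3": "f4 f8 f4 f7 f8 f8 * f8 f2",
    },
    delta=3,
    # c3 ≺ c2: s3 diverged more recently, s2 earlier; smallest first
    species_order=("s3", "s2"),
    expected={
        "focal": "f8",
        "synteny_witnesses": {
            _fs("f8", "f2"): {("c2", 8), ("c2", 9), ("c3", 8), ("c3", 9)},
            _fs("f4", "f8"): {
                ("c2", 7),
                ("c2", 9),
                ("c3", 1),
                ("c3", 2),
                ("c3", 3),
                ("c3", 5),
            },
        },
        "weak_bond_witness": ("c2", 9),
        "orthologous": _fs("f4", "f8"),
        "paralogous": _fs("f8", "f2"),
        "paralogous_witness": {("c2", 8), ("c3", 8), ("c3", 9)},
    },
)


def load_example(example_id: int) -> WorkedExample:
    """Return a worked example (1–6) with its expected outputs."""
    try:
        return _EXAMPLES[example_id]
    except KeyError:
        raise KeyError(f"unknown example id: {example_id}") from None


# ---------------------------------------------------------------------------
# Brute-force oracle

_MAX_ORACLE_GENES = 25
_MAX_ORACLE_CHROMOSOMES = 6


def _oracle_guard(genomes: GenomeSet) -> None:
    if len(genomes.chromosomes) > _MAX_ORACLE_CHROMOSOMES:
        raise ValueError("oracle guard: too many chromosomes")
    for c in genomes.chromosomes:
        if len(c.assigned_genes) > _MAX_ORACLE_GENES:
            raise ValueError("oracle guard: too many genes on one chromosome")


def brute_force_subsets(
    chromosome: Chromosome, delta: int
) -> dict[frozenset[str], set[frozenset[Gene]]]:
    """All non-trivial δ-subsets by scanning every width-δ position window
    and enumerating every gene combination inside it."""
    assigned = chromosome.assigned_genes
    out: dict[frozenset[str], set[frozenset[Gene]]] = {}
    if not assigned:
        return out
    top = assigned[-1].position
    for start in range(1, top + 1):
        inside = [g for g in assigned if start <= g.position <= start + delta - 1]
        for r in range(2, len(inside) + 1):
            for combo in itertools.combinations(inside, r):
                fams = frozenset(g.family for g in combo)
                if len(fams) >= 2:
                    out.setdefault(fams, set()).add(frozenset(combo))
    return out


def brute_force_syntenies(genomes: GenomeSet, delta: int) -> tuple[Synteny, ...]:
    """Independent end-to-end derivation of the maximal δ-syntenies.

    Enumerates all δ-segments per chromosome exhaustively, intersects family
    sets across chromosomes for clusters, and applies the maximality
    (witness-coverage) rule literally, smallest clusters first.
    """
    _oracle_guard(genomes)
    per_family: dict[frozenset[str], dict[tuple[str, str], set[Gene]]] = {}
    for c in genomes.chromosomes:
        for fams, segs in brute_force_subsets(c, delta).items():
            genes = set().union(*segs)
            per_family.setdefault(fams, {})[c.key] = genes
    clusters = []
    for fams, per_chrom in per_family.items():
        if len(per_chrom) < 2:
            continue
        witness = frozenset(g for gs in per_chrom.values() for g in gs)
        clusters.append(
            DeltaCluster(
                families=fams,
                witness=witness,
                chromosome_cover=frozenset(per_chrom),
            )
        )
    # literal Def-style maximality check, increasing family-set size
    clusters.sort(key=lambda c: (len(c.families), tuple(sorted(c.families))))
    survivors = []
    for small in clusters:
        absorbed = any(
            small.families < big.families and small.witness <= big.witness
            for big in clusters
        )
        if not absorbed:
            survivors.append(
                Synteny(
                    families=small.families,
                    witness=small.witness,
                    chromosome_cover=small.chromosome_cover,
                )
            )
    return tuple(sorted(survivors, key=DeltaCluster.sort_key))


def random_genome_set(
    seed: int,
    n_chromosomes: int = 3,
    max_genes: int = 15,
    n_families: int = 6,
    unassigned_prob: float = 0.2,
    n_species: int | None = None,
) -> GenomeSet:
    """A small random genome set for oracle-vs-implementation sweeps."""
    rng = np.random.default_rng(seed)
    pool = [f"f{i}" for i in range(1, n_families + 1)]
    chroms = []
    n_species = n_species or n_chromosomes
    for i in range(n_chromosomes):
        n = int(rng.integers(2, max_genes + 1))
        tokens = [
            UNASSIGNED
            if rng.random() < unassigned_prob
            else pool[int(rng.integers(0, len(pool)))]
            for _ in range(n)
        ]
        sp = f"sp{(i % n_species) + 1}"
        chroms.append(
            parse_compact_notation(" ".join(tokens), sp, f"chr{i + 1}")
        )
    return GenomeSet(chroms)


# ---------------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class PlantedCluster:
    """A conserved cluster to plant: a family set placed, in shuffled order,
    on one chromosome of each carrier species with bounded internal gaps."""

    name: str
    families: tuple[str, ...]
    species: tuple[str, ...] | None = None  # None = all species
    max_internal_gap: int = 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters.

    Defaults emulate a small multi-genome study: five species (the size of
    the clade the method was evaluated on), two chromosomes each, and a few
    dozen background genes per chromosome. ``cluster_spacing`` keeps planted
    runs far enough apart that distinct clusters cannot bridge.
    """

    species_count: int = 5
    chromosomes_per_species: int = 2
    genes_per_chromosome: int = 40
    planted_clusters: tuple[PlantedCluster, ...] = ()
    paralog_rate: float = 0.0
    loss_rate: float = 0.0
    background_unassigned_fraction: float = 0.1
    cluster_spacing: int = 10
    seed: int = 0

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(f"sp{i + 1}" for i in range(self.species_count))


@dataclass(frozen=True)
class GroundTruth:
    """Planted-cluster membership: cluster name -> species -> gene ids."""

    clusters: dict[str, dict[str, tuple[str, ...]]]
    paralog_copies: frozenset[str] = field(default_factory=frozenset)

    def gene_ids(self, name: str) -> set[str]:
        return {g for per_sp in self.clusters[name].values() for g in per_sp}


def _planted_run(
    cluster: PlantedCluster, rng: np.random.Generator, paralog_rate: float,
    loss_rate: float,
) -> tuple[list[str], list[bool]]:
    """Token run for one species: shuffled families, internal gaps, optional
    tandem paralog copies; returns tokens plus a planted-flag per token."""
    fams = list(cluster.families)
    rng.shuffle(fams)
    tokens: list[str] = []
    flags: list[bool] = []
    for i, fam in enumerate(fams):
        if loss_rate > 0 and rng.random() < loss_rate:
            continue
        if i > 0 and tokens:
            for _ in range(int(rng.integers(0, cluster.max_internal_gap + 1))):
                tokens.append(UNASSIGNED)
                flags.append(False)
        tokens.append(fam)
        flags.append(True)
        if paralog_rate > 0 and rng.random() < paralog_rate:
            tokens.append(fam)  # tandem copy
            flags.append(True)
    return tokens, flags


def generate(spec: SyntheticSpec) -> tuple[GenomeSet, GroundTruth]:
    """Generate a genome set with planted conserved clusters.

    Deterministic given ``spec.seed``. Background positions carry either a
    unique singleton family (which can never witness a cross-chromosome
    cluster) or the unassigned marker. Planted runs are spliced between
    background stretches of at least ``cluster_spacing`` positions.
    """
    rng = np.random.default_rng(spec.seed)
    truth: dict[str, dict[str, list[str]]] = {c.name: {} for c in spec.planted_clusters}
    paralog_ids: set[str] = set()
    bg_counter = itertools.count(1)
    chroms = []
    for sp in spec.species:
        # assign each planted run for this species to a chromosome
        runs_per_chrom: dict[int, list[PlantedCluster]] = {
            i: [] for i in range(spec.chromosomes_per_species)
        }
        for cluster in spec.planted_clusters:
            carriers = cluster.species or spec.species
            if sp not in carriers:
                continue
            runs_per_chrom[int(rng.integers(0, spec.chromosomes_per_species))].append(
                cluster
            )
        for ci in range(spec.chromosomes_per_species):
            runs = runs_per_chrom[ci]
            n_bg = spec.genes_per_chromosome
            need = max(0, len(runs) - 1) * spec.cluster_spacing
            if runs and n_bg < need + 1:
                raise ValueError(
                    f"infeasible placement: {len(runs)} runs need at least "
                    f"{need + 1} background positions, chromosome has {n_bg}"
                )
            # cut points where runs are spliced into the background; the
            # sorted-sample-plus-offset trick keeps consecutive cuts at
            # least cluster_spacing apart
            if runs:
                base = np.sort(
                    rng.integers(0, n_bg - need + 1, size=len(runs))
                )
                cuts = [
                    int(b) + k * spec.cluster_spacing for k, b in enumerate(base)
                ]
            else:
                cuts = []
            tokens: list[str] = []
            flags: list[tuple[str, bool] | None] = []
            prev = 0
            segments = list(zip(cuts, runs)) + [(n_bg, None)]
            for cut, cluster in segments:
                for _ in range(cut - prev):
                    if rng.random() < spec.background_unassigned_fraction:
                        tokens.append(UNASSIGNED)
                    else:
                        tokens.append(f"B{next(bg_counter)}")
                    flags.append(None)
                prev = cut
                if cluster is not None:
                    run_tokens, run_flags = _planted_run(
                        cluster, rng, spec.paralog_rate, spec.loss_rate
                    )
                    tokens.extend(run_tokens)
                    flags.extend(
                        (cluster.name, planted) if planted else None
                        for planted in run_flags
                    )
            chrom_id = f"chr{ci + 1}"
            genes = tuple(
                Gene(
                    species=sp,
                    chromosome=chrom_id,
                    position=k,
                    family=tok,
                    gene_id=f"{sp}:{chrom_id}:{k}",
                )
                for k, tok in enumerate(tokens, start=1)
            )
            chrom = Chromosome(species=sp, chromosome_id=chrom_id, genes=genes)
            chroms.append(chrom)
            seen_fams: dict[str, int] = {}
            for g, flag in zip(genes, flags):
                if flag is None:
                    continue
                name, _ = flag
                truth[name].setdefault(sp, []).append(g.gene_id)
                count = seen_fams.get(g.family, 0)
                if count:  # later same-family copies in one run are paralogs
                    paralog_ids.add(g.gene_id)
                seen_fams[g.family] = count + 1
    order = SpeciesOrder(spec.species)
    genomes = GenomeSet(chroms, species_order=order)
    ground = GroundTruth(
        clusters={
            name: {sp: tuple(ids) for sp, ids in per_sp.items()}
            for name, per_sp in truth.items()
        },
        paralog_copies=frozenset(paralog_ids),
    )
    return genomes, ground
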