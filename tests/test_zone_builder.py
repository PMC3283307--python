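"""Zone agglomeration, weak-bond resolution and the SYNS driver."""

import pytest

from synteams.genome_model import Gene, GenomeSet, parse_compact_notation
from synteams.synteny_core import Synteny
from synteams.validation_fixtures import load_example
from synteams.zone_builder import (
    ORTHOLOGOUS,
    PARALOGOUS,
    SpeciesOrder,
    WeakBond,
    agglomerate_zones,
    resolve_weak_bond,
    syns_run,
)

from conftest import famsets


def _synteny(families, witness):
    return Synteny(
        families=frozenset(families),
        witness=frozenset(witness),
        chromosome_cover=frozenset(g.chromosome_key for g in witness),
    )


def _gene(species, chrom, pos, fam):
    return Gene(species=species, chromosome=chrom, position=pos, family=fam)


class TestAgglomeration:
    def test_printed_two_synteny_agglomeration(self):
        """The two printed syntenies share two witness genes and fuse into a
        single zone; the stray same-family gene stays outside."""
        ex = load_example(5)
        gs = ex.genome_set()
        w = ex.expected["synteny_witnesses"]

        def genes(fs):
            return {
                gs.chromosome(f"s{c[1:]}", c).gene_at(p) for c, p in w[fs]
            }

        s1 = _synteny({"f7", "f8"}, genes(frozenset({"f7", "f8"})))
        s2 = _synteny({"f4", "f8"}, genes(frozenset({"f4", "f8"})))
        assert len(s1.witness & s2.witness) >= 2
        zones, bonds = agglomerate_zones([s1, s2])
        assert len(zones) == 1 and not bonds
        assert zones[0].families == ex.expected["zone_families"]
        excluded = ex.gene("c3", 8)
        assert excluded not in zones[0].witness

    def test_disjoint_witnesses_stay_separate(self):
        a = _synteny({"f1", "f2"}, {_gene("s1", "c1", 1, "f1"), _gene("s2", "c2", 1, "f2")})
        b = _synteny({"f3", "f4"}, {_gene("s1", "c1", 9, "f3"), _gene("s2", "c2", 9, "f4")})
        zones, bonds = agglomerate_zones([a, b])
        assert len(zones) == 2 and not bonds

    def test_transitive_chain_fuses_into_one_zone(self):
        shared_ab = {_gene("s1", "c1", i, "f2") for i in (1, 2)}
        shared_bc = {_gene("s2", "c2", i, "f3") for i in (5, 6)}
        a = _synteny({"f1", "f2"}, shared_ab | {_gene("s2", "c2", 1, "f1")})
        b = _synteny({"f2", "f3"}, shared_ab | shared_bc)
        c = _synteny({"f3", "f4"}, shared_bc | {_gene("s1", "c1", 9, "f4")})
        zones, bonds = agglomerate_zones([a, b, c])
        assert len(zones) == 1
        assert zones[0].families == {"f1", "f2", "f3", "f4"}
        assert len(a.witness & c.witness) == 0  # only transitively connected


class TestWeakBondResolution:
    ORDER = SpeciesOrder(("sp1", "sp2", "sp3"))  # sp3 diverged earliest

    def _bond(self, g_species):
        """Small witness spans sp1..sp3; bond gene from ``g_species``."""
        g = _gene(g_species, "cX", 5, "f8")
        big = _synteny(
            {"f4", "f8"},
            {g} | {_gene("sp1", "cA", i, "f4") for i in (1, 2, 3)}
            | {_gene("sp2", "cB", 1, "f8")},
        )
        small = _synteny(
            {"f8", "f2"},
            {g}
            | {_gene("sp1", "cC", 1, "f2"), _gene("sp3", "cD", 1, "f2")},
        )
        return WeakBond(synteny_i=big, synteny_j=small, witness_gene=g), big, small

    def test_plausible_when_bond_gene_in_oldest_lineage_present(self):
        bond, big, small = self._bond("sp3")
        res = resolve_weak_bond(bond, self.ORDER)
        assert res.plausible
        assert res.orthologous == big
        assert res.paralogous.witness == small.witness - {bond.witness_gene}

    def test_refused_when_older_lineage_witness_exists(self):
        # bond gene from sp1 while the small witness also holds sp3 genes
        bond, big, small = self._bond("sp1")
        res = resolve_weak_bond(bond, self.ORDER)
        assert not res.plausible
        assert res.orthologous == big
        assert bond.witness_gene not in res.paralogous.witness

    def test_intersection_of_two_is_not_a_weak_bond(self):
        shared = {_gene("sp1", "cA", 1, "f8"), _gene("sp2", "cB", 1, "f8")}
        a = _synteny({"f1", "f8"}, shared | {_gene("sp2", "cB", 3, "f1")})
        b = _synteny({"f2", "f8"}, shared | {_gene("sp1", "cA", 3, "f2")})
        bond = WeakBond(synteny_i=a, synteny_j=b, witness_gene=next(iter(shared)))
        with pytest.raises(ValueError):
            resolve_weak_bond(bond, self.ORDER)


class TestWorkedWeakBondExample:
    def test_two_syntenies_one_bond_ortho_para_split(self):
        ex = load_example(6)
        res = syns_run(ex.genome_set(), ex.delta, families=[ex.expected["focal"]])
        assert famsets(res.syntenies) == set(ex.expected["synteny_witnesses"])
        for fs, positions in ex.expected["synteny_witnesses"].items():
            s = next(s for s in res.syntenies if s.families == fs)
            assert {(g.chromosome, g.position) for g in s.witness} == positions
        (bond,) = res.weak_bonds
        assert (bond.witness_gene.chromosome, bond.witness_gene.position) == (
            ex.expected["weak_bond_witness"]
        )
        (resolution,) = res.resolutions
        assert resolution.plausible
        assert resolution.orthologous.families == ex.expected["orthologous"]
        assert resolution.paralogous.families == ex.expected["paralogous"]
        assert {
            (g.chromosome, g.position) for g in resolution.paralogous.witness
        } == ex.expected["paralogous_witness"]

    def test_family_splits_into_ortho_para_singleton(self):
        ex = load_example(6)
        res = syns_run(ex.genome_set(), ex.delta, families=["f8"])
        kinds = {
            sg.kind: {(g.chromosome, g.position) for g in sg.genes}
            for sg in res.partition["f8"]
        }
        assert kinds["ortholog"] == {("c2", 9), ("c3", 2), ("c3", 5)}
        assert kinds["paralog"] == {("c3", 8)}
        assert kinds["singleton"] == {("c3", 6)}

    def test_ortho_and_para_subgroups_are_disjoint(self):
        ex = load_example(6)
        res = syns_run(ex.genome_set(), ex.delta)
        for fam, subgroups in res.partition.by_family.items():
            seen = set()
            for sg in subgroups:
                assert not (seen & sg.genes)
                seen |= sg.genes


class TestSynsRun:
    def test_worked_single_zone_pipeline(self):
        ex = load_example(5)
        res = syns_run(ex.genome_set(), ex.delta, families=[ex.expected["focal"]])
        zones = res.nontrivial_zones
        assert len(zones) == 1
        assert zones[0].families == ex.expected["zone_families"]
        assert ex.gene("c3", 8) not in zones[0].witness
        assert zones[0].label == ORTHOLOGOUS

    def test_single_chromosome_all_singletons(self):
        gs = GenomeSet([parse_compact_notation("f1 f2 f1 f3", "s1", "c1")])
        res = syns_run(gs, 3)
        assert res.zones == ()
        assert all(
            sg.kind == "singleton"
            for sg in res.partition.subgroups()
        )

    def test_locality_unrelated_chromosome_changes_nothing(self):
        ex = load_example(5)
        base = syns_run(ex.genome_set(), 3, families=["f8"])
        extra = parse_compact_notation("g1 g2 g3", "s9", "c9")
        augmented = GenomeSet(
            list(ex.genome_set().chromosomes) + [extra]
        )
        after = syns_run(augmented, 3, families=["f8"])
        assert {(z.families, z.witness) for z in base.zones} == {
            (z.families, z.witness) for z in after.zones
        }

    def test_weak_bond_without_species_order_is_an_error(self):
        ex = load_example(6)
        chroms = ex.genome_set().chromosomes
        gs = GenomeSet(chroms)  # no order attached
        with pytest.raises(ValueError):
            syns_run(gs, 3, families=["f8"])

    def test_larger_of_two_ortho_zones_retained(self):
        """Two disjoint conserved neighborhoods of one family: only the one
        with more witness genes of the family stays orthologous; the other's
        members fall back to singletons."""
        gs = GenomeSet(
            [
                parse_compact_notation("f1 f2 * f1 * * * * f1 f3", "s1", "c1"),
                parse_compact_notation("f1 f2 * f1 * * * * f1 f3", "s2", "c2"),
            ]
        )
        res = syns_run(gs, 3)
        zones = {z.families: z for z in res.nontrivial_zones}
        assert set(zones) == {frozenset({"f1", "f2"}), frozenset({"f1", "f3"})}
        kinds = {sg.kind for sg in res.partition["f1"]}
        assert kinds == {"ortholog", "singleton"}
        ortho = next(
            sg for sg in res.partition["f1"] if sg.kind == "ortholog"
        )
        # the {f1,f2} neighborhood holds four f1 witnesses (two per species)
        assert len(ortho.genes) == 4
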