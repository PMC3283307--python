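"""Accounting scheme for comparing two orthologous-group classifications.

Two classifications over (partially) overlapping gene universes are compared
on their common universe through the bipartite overlap graph between groups:
a connected component that is one-to-one is *identical*; one a-group facing
several b-groups is a *split*; the symmetric case a *merge*; anything bigger
is *messy*. Genes covered by exactly one side are counted separately, as are
genes the b side leaves in size-1 groups.

The similarity value is the mean, over common-universe genes, of the Jaccard
index between the gene's two groups (restricted to the common universe).
This is a declared substitute for the externally defined similarity of the
original report and is labelled as such in emitted summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

__all__ = ["Classification", "ComparisonReport", "compare"]

SIMILARITY_LEGEND = (
    "similarity = mean per-gene Jaccard index over the common universe "
    "(substitute metric); singletons = genes grouped alone by the second "
    "classification while covered by the first"
)


class Classification:
    """A named partition of a gene universe into groups."""

    def __init__(self, name: str, groups: Mapping[str, Iterable[str]]) -> None:
        self.name = name
        self.groups: dict[str, frozenset[str]] = {}
        seen: dict[str, str] = {}
        for gid, genes in groups.items():
            members = frozenset(genes)
            if not members:
                raise ValueError(f"{name}: group {gid} is empty")
            for g in members:
                if g in seen:
                    raise ValueError(
                        f"{name}: gene {g} appears in groups {seen[g]} and {gid}"
                    )
                seen[g] = gid
            self.groups[gid] = members
        self.universe: frozenset[str] = frozenset(seen)
        self._group_of = seen

    def group_of(self, gene: str) -> str:
        return self._group_of[gene]

    def __len__(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class ComparisonReport:
    a_name: str
    b_name: str
    identical_groups: int
    similarity: float
    only_in_a: int
    only_in_b: int
    singletons: int
    merges: int
    splits: int
    messy: int

    def summary(self) -> str:
        lines = [
            f"comparison: {self.a_name} vs {self.b_name}",
            f"  identical groups : {self.identical_groups}",
            f"  similarity       : {self.similarity:.3f}",
            f"  only in {self.a_name:<9}: {self.only_in_a} genes",
            f"  only in {self.b_name:<9}: {self.only_in_b} genes",
            f"  singletons       : {self.singletons}",
            f"  merges           : {self.merges}",
            f"  splits           : {self.splits}",
            f"  messy            : {self.messy}",
            f"  [{SIMILARITY_LEGEND}]",
        ]
        return "\n".join(lines)


def compare(a: Classification, b: Classification) -> ComparisonReport:
    """Compare classification ``a`` against ``b`` (the refinement side).

    A *split* is an a-group split into several b-groups, a *merge* the
    opposite; see the module docstring for the full component rules.
    """
    common = a.universe & b.universe
    only_in_a = len(a.universe - b.universe)
    only_in_b = len(b.universe - a.universe)

    a_restricted = {
        gid: members & common for gid, members in a.groups.items() if members & common
    }
    b_restricted = {
        gid: members & common for gid, members in b.groups.items() if members & common
    }
    graph = nx.Graph()
    graph.add_nodes_from(("a", gid) for gid in a_restricted)
    graph.add_nodes_from(("b", gid) for gid in b_restricted)
    for g in common:
        graph.add_edge(("a", a.group_of(g)), ("b", b.group_of(g)))

    identical = merges = splits = messy = 0
    for comp in nx.connected_components(graph):
        a_side = [gid for side, gid in comp if side == "a"]
        b_side = [gid for side, gid in comp if side == "b"]
        if len(a_side) == 1 and len(b_side) == 1:
            if a_restricted[a_side[0]] == b_restricted[b_side[0]]:
                identical += 1
            else:  # unreachable for partitions; kept for safety
                messy += 1
        elif len(a_side) == 1 and len(b_side) >= 2:
            splits += 1
        elif len(a_side) >= 2 and len(b_side) == 1:
            merges += 1
        else:
            messy += 1

    singletons = sum(
        1
        for gid, members in b.groups.items()
        if len(members) == 1 and next(iter(members)) in a.universe
    )
    if common:
        total = 0.0
        for g in common:
            ga = a_restricted[a.group_of(g)]
            gb = b_restricted[b.group_of(g)]
            total += len(ga & gb) / len(ga | gb)
        similarity = total / len(common)
    else:
        similarity = 0.0

    return ComparisonReport(
        a_name=a.name,
        b_name=b.name,
        identical_groups=identical,
        similarity=similarity,
        only_in_a=only_in_a,
        only_in_b=only_in_b,
        singletons=singletons,
        merges=merges,
        splits=splits,
        messy=messy,
    )
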