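"""Weighted driver-set catalogs for consensus (Borda-style) gene scoring.

A catalog is a collection of named driver-gene sets partitioned into
Group1 (gold-standard evidence, weight 10) and Group2 (supplementary
evidence, weight 1).  A gene's consensus score is the sum of the
weights of every set that contains it; membership is matched
case-insensitively on the HUGO symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

__all__ = ["DriverSet", "DriverSetCatalog", "DEFAULT_GROUP1_NAMES",
           "GROUP1_WEIGHT", "GROUP2_WEIGHT", "SIGNIFICANCE_SET_NAME"]

GROUP1_WEIGHT = 10
GROUP2_WEIGHT = 1

#: Name under which the combined-significance gene set is injected.
SIGNIFICANCE_SET_NAME = "AI-DriverGene"

#: The four gold-standard catalogs carrying weight 10 by default.
DEFAULT_GROUP1_NAMES = ("CGC", "OncoKB", SIGNIFICANCE_SET_NAME, "MutPanning")


@dataclass(frozen=True)
class DriverSet:
    name: str
    members: frozenset[str]  # normalized (upper-case) symbols
    group1: bool

    @property
    def weight(self) -> int:
        return GROUP1_WEIGHT if self.group1 else GROUP2_WEIGHT


@dataclass
class DriverSetCatalog:
    """Named gene sets with Group1/Group2 weights."""

    sets: dict[str, DriverSet] = field(default_factory=dict)
    group1_names: tuple[str, ...] = DEFAULT_GROUP1_NAMES

    def add_set(self, name: str, members: Iterable[str], group1: bool | None = None) -> None:
        if group1 is None:
            group1 = name in self.group1_names
        norm = frozenset(m.strip().upper() for m in members if m.strip())
        self.sets[name] = DriverSet(name=name, members=norm, group1=group1)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def weight(self, name: str) -> int:
        return self.sets[name].weight

    def score(self, gene: str) -> int:
        """Consensus score: sum of weights of sets containing the gene."""
        g = gene.strip().upper()
        return sum(s.weight for s in self.sets.values() if g in s.members)

    def all_members(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s.members
        return out
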