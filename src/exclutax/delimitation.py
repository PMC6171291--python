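"""Species assignment: largest exclusive groups meeting a joint ANI/AF cutoff.

Species are equated with the most inclusive clades of the UPGMA tree of the
average patristic distance matrix that (a) are exclusive (score > -slack)
and (b) satisfy the similarity criterion — every within-group pair meets
ANI >= ani_min and AF >= af_min (complete linkage), or the within-group
threshold graph is connected (single linkage; a "single_literal" mode only
requires each member to pair with at least one other member, which can
admit disconnected groups).  Genomes in no qualifying group become
singleton species, which are trivially exclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import dendropy
import numpy as np

from .clustering import upgma
from .core import AnalysisConfig, DistanceMatrix, PairSimilarityTable, logger
from .exclusivity import score_clades

__all__ = [
    "pair_meets_threshold",
    "SpeciesPartition",
    "delimit_species",
    "SplitReport",
    "split_report",
    "PartitionSummary",
    "summarize_partition",
]


def pair_meets_threshold(
    a: str, b: str, table: PairSimilarityTable, cfg: AnalysisConfig
) -> bool:
    """True iff the unordered pair satisfies ANI >= ani_min and AF >= af_min.

    Pairs absent from the table fail the criterion (conservative: splits
    rather than lumps), with a warning.
    """
    values = table.get(a, b)
    if values is None:
        logger.warning("pair (%s, %s) absent from the similarity table; treated as failing", a, b)
        return False
    ani, af = values
    return ani >= cfg.ani_min and af >= cfg.af_min


@dataclass
class SpeciesPartition:
    """Disjoint cover of all genomes into ranked species groups."""

    groups: list[tuple[str, ...]]
    provenance: list[str]  # "clade" or "singleton" per group
    linkage: str
    ani_min: float
    af_min: float
    slack: float

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for group in self.groups:
            if seen & set(group):
                raise ValueError("species groups are not disjoint")
            seen.update(group)

    @property
    def genomes(self) -> set[str]:
        return {g for group in self.groups for g in group}

    def species_of(self) -> dict[str, int]:
        return {g: i for i, group in enumerate(self.groups) for g in group}

    def to_tsv(self) -> str:
        lines = ["genome\tspecies\tprovenance\tgroup_size"]
        for i, (group, prov) in enumerate(zip(self.groups, self.provenance)):
            for g in group:
                lines.append(f"{g}\tsp{i + 1:04d}\t{prov}\t{len(group)}")
        return "\n".join(lines) + "\n"


def _linkage_ok(
    group: Sequence[str], table: PairSimilarityTable, cfg: AnalysisConfig
) -> bool:
    if len(group) < 2:
        return True
    if cfg.linkage == "complete":
        return all(
            pair_meets_threshold(a, b, table, cfg) for a, b in combinations(group, 2)
        )
    if cfg.linkage == "single_literal":
        # each member pairs with at least one other member; permits groups
        # whose threshold graph is disconnected
        for a in group:
            if not any(
                pair_meets_threshold(a, b, table, cfg) for b in group if b != a
            ):
                return False
        return True
    # single linkage proper: the within-group threshold graph is connected
    # (which implies every member pairs with at least one other member)
    remaining = set(group)
    stack = [group[0]]
    remaining.discard(group[0])
    while stack:
        a = stack.pop()
        linked = [b for b in remaining if pair_meets_threshold(a, b, table, cfg)]
        for b in linked:
            remaining.discard(b)
        stack.extend(linked)
    return not remaining


def delimit_species(
    d: DistanceMatrix,
    table: PairSimilarityTable,
    cfg: AnalysisConfig,
    tree: dendropy.Tree | None = None,
) -> SpeciesPartition:
    """Assign every genome to the most inclusive qualifying exclusive clade.

    Builds the UPGMA tree of ``d`` (or uses ``tree`` if given), scores every
    clade, then walks root-down: the first clade that is exclusive at the
    configured slack and satisfies the linkage criterion becomes a species
    and its subtree is not descended further.  The root (full set) is
    unscorable and never a species.  Leaves reached without a qualifying
    clade become singleton species.
    """
    if tree is None:
        tree, _ = upgma(d)
    slack = cfg.exclusivity_slack
    scored = {id(node): rec for node, rec in score_clades(tree, d)}
    groups: list[tuple[str, ...]] = []
    provenance: list[str] = []

    def descend(node: dendropy.Node) -> None:
        if node.is_leaf():
            groups.append((node.taxon.label,))
            provenance.append("singleton")
            return
        rec = scored.get(id(node))
        if rec is not None and rec.is_exclusive(slack) and _linkage_ok(rec.group, table, cfg):
            groups.append(rec.group)
            provenance.append("clade")
            return
        for child in node.child_nodes():
            descend(child)

    for child in tree.seed_node.child_nodes():
        descend(child)
    order = sorted(range(len(groups)), key=lambda i: (-len(groups[i]), groups[i]))
    return SpeciesPartition(
        groups=[groups[i] for i in order],
        provenance=[provenance[i] for i in order],
        linkage=cfg.linkage,
        ani_min=cfg.ani_min,
        af_min=cfg.af_min,
        slack=slack,
    )


@dataclass
class SplitReport:
    """How often the exclusivity requirement splits similar genome pairs."""

    meeting_pairs: int
    split_pairs: int

    @property
    def ratio(self) -> float:
        return self.split_pairs / self.meeting_pairs if self.meeting_pairs else 0.0


def split_report(
    partition: SpeciesPartition, table: PairSimilarityTable, cfg: AnalysisConfig
) -> SplitReport:
    """Count threshold-meeting genome pairs placed in different species."""
    genomes = sorted(partition.genomes)
    missing = table.genomes() - set(genomes)
    if missing:
        raise ValueError(f"partition does not cover genomes: {sorted(missing)}")
    species = partition.species_of()
    meeting = 0
    split = 0
    for a, b in combinations(genomes, 2):
        if pair_meets_threshold(a, b, table, cfg):
            meeting += 1
            if species[a] != species[b]:
                split += 1
    return SplitReport(meeting_pairs=meeting, split_pairs=split)


@dataclass
class PartitionSummary:
    species_count: int
    singleton_count: int
    largest_species: int
    mean_genomes_per_species: float


def summarize_partition(partition: SpeciesPartition) -> PartitionSummary:
    sizes = [len(g) for g in partition.groups]
    return PartitionSummary(
        species_count=len(sizes),
        singleton_count=sum(1 for s in sizes if s == 1),
        largest_species=max(sizes) if sizes else 0,
        mean_genomes_per_species=(sum(sizes) / len(sizes)) if sizes else 0.0,
    )
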