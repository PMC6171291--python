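"""Synthetic genome-collection scenarios for testing the full pipeline.

Emulates the statistical structure the analyses assume: a clock-like
species tree with planted species (shallow clades well separated from the
between-species backbone); per-gene trees made discordant by random
horizontal-transfer (subtree-prune-regraft) events at matching times, with
lognormal gene-rate variation; auxiliary gene presence/absence generated by
a single gain on a branch followed by stochastic loss below it; and ANI/AF
tables decreasing monotonically in genome distance.  Everything is driven
by one integer-seeded generator, so a scenario is byte-reproducible.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .core import (
    DistanceMatrix,
    PairSimilarityTable,
    PresenceAbsenceMatrix,
    RunManifest,
    read_newick,
)
from . import core as _core
from .treemetrics import average_matrices, patristic_matrix

import pandas as pd

__all__ = [
    "ScenarioSpec",
    "ScenarioData",
    "simulate_species_tree",
    "simulate_gene_trees",
    "simulate_presence_absence",
    "simulate_pair_similarity",
    "random_topology",
    "generate_scenario",
    "write_scenario",
]


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic genome collection.

    Depth units are substitutions per site on the species tree, whose root
    sits at height 1.  ``species_crown_max`` bounds within-species node
    heights and ``backbone_min`` bounds between-species node heights, so the
    planted species are exactly the clades below the separation.  The
    default ``transfer_mean`` (expected transfer events per gene tree) is
    calibrated so the mean between-gene patristic R^2 on the default
    scenario is near the 0.44 level typical of real core genes.
    """

    n_taxa: int = 60
    n_species: int = 12
    speciation_rate: float = 1.0
    species_crown_max: float = 0.05
    backbone_min: float = 0.25
    n_genes: int = 50
    transfer_mean: float = 5.0
    rate_sigma: float = 0.3
    n_aux_clusters: int = 400
    loss_rate: float = 0.4
    ani_scale: float = 0.3
    ani_noise_sd: float = 0.25
    af_max: float = 0.95
    af_scale: float = 2.0
    af_noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("need at least 4 taxa")
        if not (1 <= self.n_species <= self.n_taxa):
            raise ValueError("n_species must lie in [1, n_taxa]")
        if self.species_crown_max >= self.backbone_min:
            raise ValueError("species_crown_max must be below backbone_min")
        for name in (
            "speciation_rate",
            "transfer_mean",
            "rate_sigma",
            "loss_rate",
            "ani_scale",
            "ani_noise_sd",
            "af_scale",
            "af_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


class _Node:
    """Minimal clock-tree node: age in time units, children, leaf label."""

    __slots__ = ("age", "children", "label")

    def __init__(self, age: float, children: list["_Node"] | None = None, label: str | None = None):
        self.age = age
        self.children = children or []
        self.label = label

    def leaves(self) -> list["_Node"]:
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        def fmt(node: "_Node", parent_age: float) -> str:
            length = parent_age - node.age
            if not node.children:
                return f"{node.label}:{length:.10g}"
            inner = ",".join(fmt(c, node.age) for c in node.children)
            return f"({inner}):{length:.10g}"

        inner = ",".join(fmt(c, self.age) for c in self.children)
        return f"({inner});"


def _random_joins(
    tips: list[_Node], heights: Sequence[float], rng: np.random.Generator
) -> _Node:
    """Agglomerate tips bottom-up at the given ascending join heights."""
    lineages = list(tips)
    for h in heights:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        merged = _Node(age=float(h), children=[lineages[i], lineages[j]])
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append(merged)
    assert len(lineages) == 1
    return lineages[0]


def _to_dendropy(root: _Node) -> dendropy.Tree:
    return read_newick(root.newick())


def _build_species_structure(
    spec: ScenarioSpec, rng: np.random.Generator
) -> tuple[_Node, dict[str, tuple[str, ...]]]:
    k = spec.n_species
    sizes = [spec.n_taxa // k] * k
    for i in range(spec.n_taxa % k):
        sizes[i] += 1
    label_iter = iter(f"G{i + 1:04d}" for i in range(spec.n_taxa))
    truth: dict[str, tuple[str, ...]] = {}
    species_roots: list[_Node] = []
    for si, size in enumerate(sizes):
        labels = [next(label_iter) for _ in range(size)]
        truth[f"species{si + 1:03d}"] = tuple(labels)
        tips = [_Node(0.0, label=l) for l in labels]
        if size == 1:
            species_roots.append(tips[0])
            continue
        heights = np.sort(rng.uniform(0.0, spec.species_crown_max, size - 1))
        species_roots.append(_random_joins(tips, heights, rng))
    if k == 1:
        return species_roots[0], truth
    # Yule waiting times between successive backbone splits, then rescaled so
    # the shallowest backbone node sits at backbone_min and the root at 1.
    waits = rng.exponential(
        1.0 / (spec.speciation_rate * np.arange(2, k + 1)), size=k - 1
    )
    ages = np.cumsum(waits)
    if k == 2:
        ages = np.array([1.0])
    else:
        lo, hi = ages.min(), ages.max()
        ages = spec.backbone_min + (ages - lo) * (1.0 - spec.backbone_min) / (hi - lo)
    root = _random_joins(species_roots, np.sort(ages), rng)
    return root, truth


def simulate_species_tree(
    spec: ScenarioSpec, rng: np.random.Generator | None = None
) -> tuple[dendropy.Tree, dict[str, tuple[str, ...]]]:
    """Clock-like species tree with planted species; returns (tree, truth).

    ``truth`` maps species names to their member genome labels; planted
    species are exactly the maximal clades below ``species_crown_max``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    root, truth = _build_species_structure(spec, rng)
    return _to_dendropy(root), truth


def _alive_edges(root: _Node, t: float) -> list[tuple[_Node, _Node]]:
    """(parent, child) edges spanning time t (child.age < t < parent.age)."""
    out = []
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if child.age < t < node.age:
                out.append((node, child))
            stack.append(child)
    # deterministic order for reproducible sampling
    out.sort(key=lambda pc: min(l.label for l in pc[1].leaves()))
    return out


def _apply_transfer(root: _Node, t: float, rng: np.random.Generator) -> _Node:
    """One horizontal transfer: re-attach a lineage alive at time t elsewhere."""
    alive = _alive_edges(root, t)
    if len(alive) < 2:
        return root
    i, j = rng.choice(len(alive), size=2, replace=False)
    (rp, rc) = alive[int(i)]  # recipient lineage: subtree that moves
    (dp, dc) = alive[int(j)]  # donor edge: attachment point
    # insert a new node at age t on the donor edge
    joint = _Node(age=t, children=[dc, rc])
    dp.children[dp.children.index(dc)] = joint
    # detach the moved lineage and suppress its old unifurcating parent
    rp.children.remove(rc)
    if len(rp.children) == 1:
        only = rp.children[0]
        parent = _find_parent(root, rp)
        if parent is None:
            root = only
        else:
            parent.children[parent.children.index(rp)] = only
    return root


def _find_parent(root: _Node, target: _Node) -> _Node | None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in node.children:
            if child is target:
                return node
            stack.append(child)
    return None


def _scale_ages(node: _Node, factor: float) -> None:
    node.age *= factor
    for child in node.children:
        _scale_ages(child, factor)


def _internal_from_dendropy(tree: dendropy.Tree) -> _Node:
    """Rebuild the internal clock representation (ages) from a dendropy tree."""

    def depth_build(node: dendropy.Node) -> tuple[_Node, float]:
        if node.is_leaf():
            return _Node(0.0, label=node.taxon.label), 0.0
        built = []
        depths = []
        for child in node.child_nodes():
            sub, d = depth_build(child)
            built.append(sub)
            depths.append(d + (child.edge.length or 0.0))
        age = float(np.mean(depths))
        return _Node(age, children=built), age

    root, _ = depth_build(tree.seed_node)
    return root


def simulate_gene_trees(
    species_tree: dendropy.Tree,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> list[dendropy.Tree]:
    """Per-gene trees: species tree + Poisson-many transfers + rate factor.

    Each transfer picks a time uniformly over the tree height, then moves
    one lineage alive at that time onto another contemporaneous edge, so the
    gene tree stays clock-like.  All branch lengths are finally multiplied
    by a lognormal gene-rate factor (sigma = ``rate_sigma``).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    base = _internal_from_dendropy(species_tree)
    height = base.age
    trees = []
    for _ in range(spec.n_genes):
        gene = copy.deepcopy(base)
        n_transfers = int(rng.poisson(spec.transfer_mean))
        for _ in range(n_transfers):
            t = float(rng.uniform(0.0, height))
            gene = _apply_transfer(gene, t, rng)
        factor = float(rng.lognormal(mean=0.0, sigma=spec.rate_sigma))
        _scale_ages(gene, factor)
        trees.append(_to_dendropy(gene))
    return trees


def simulate_presence_absence(
    species_tree: dendropy.Tree,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
) -> PresenceAbsenceMatrix:
    """Gene content: all-present core clusters plus gain/loss auxiliaries.

    Each auxiliary cluster originates once, on an edge chosen with
    probability proportional to branch length, and is then lost along each
    descendant branch with probability 1 - exp(-loss_rate * length); lost
    lineages never regain it.  All-absent columns are not emitted.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    leaves = sorted(l.taxon.label for l in species_tree.leaf_node_iter())
    n = len(leaves)
    pos = {l: i for i, l in enumerate(leaves)}

    edges = []  # (child node, length)
    for node in species_tree.preorder_node_iter():
        if node.parent_node is not None:
            edges.append((node, float(node.edge.length or 0.0)))
    lengths = np.array([l for _, l in edges])
    probs = lengths / lengths.sum()

    columns: list[np.ndarray] = []
    names: list[str] = []
    core = np.ones(n, dtype=np.int64)
    for i in range(spec.n_genes):
        columns.append(core.copy())
        names.append(f"core{i + 1:05d}")
    for i in range(spec.n_aux_clusters):
        origin = edges[int(rng.choice(len(edges), p=probs))][0]
        present = np.zeros(n, dtype=np.int64)

        def evolve(node: dendropy.Node, alive: bool) -> None:
            if not alive:
                return
            if node is not origin:
                length = float(node.edge.length or 0.0)
                if rng.uniform() < 1.0 - np.exp(-spec.loss_rate * length):
                    return
            if node.is_leaf():
                present[pos[node.taxon.label]] = 1
                return
            for child in node.child_nodes():
                evolve(child, True)

        evolve(origin, True)
        if present.any():
            columns.append(present)
            names.append(f"aux{i + 1:05d}")
    counts = np.column_stack(columns)
    return PresenceAbsenceMatrix(tuple(leaves), tuple(names), counts)


def simulate_pair_similarity(
    d: DistanceMatrix,
    spec: ScenarioSpec,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> PairSimilarityTable:
    """ANI/AF decreasing monotonically in genome distance, plus noise.

    ANI(i,j) = 100 exp(-ani_scale d) + N(0, ani_noise_sd), clamped to
    [0, 100]; AF analogously from af_max exp(-af_scale d) into [0, 1].
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    rows = []
    for i in range(d.n):
        for j in range(i + 1, d.n):
            dist = d.values[i, j]
            ani = 100.0 * np.exp(-spec.ani_scale * dist)
            af = spec.af_max * np.exp(-spec.af_scale * dist)
            if not noiseless:
                ani += rng.normal(0.0, spec.ani_noise_sd)
                af += rng.normal(0.0, spec.af_noise_sd)
            rows.append(
                (
                    d.labels[i],
                    d.labels[j],
                    float(np.clip(ani, 0.0, 100.0)),
                    float(np.clip(af, 0.0, 1.0)),
                )
            )
    df = pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "af"])
    return PairSimilarityTable(df)


def random_topology(
    labels: Sequence[str], rng: np.random.Generator
) -> dendropy.Tree:
    """Uniformly random fully resolved unrooted topology on ``labels``.

    Sequential random addition: each new leaf subdivides one of the current
    2k-3 unrooted edges chosen uniformly, which yields the uniform
    distribution over labelled unrooted binary topologies.  Branch lengths
    are all 1.  Used for Monte-Carlo corroboration of the RF null.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels")
    # adjacency over integer node ids; leaves are 0..n-1
    n = len(labels)
    adj: dict[int, list[int]] = {i: [] for i in range(3)}
    center = n  # first internal node
    adj[center] = [0, 1, 2]
    for leaf in (0, 1, 2):
        adj[leaf] = [center]
    edges: list[tuple[int, int]] = [(center, 0), (center, 1), (center, 2)]
    next_internal = n + 1
    for leaf in range(3, n):
        u, v = edges[int(rng.integers(len(edges)))]
        mid = next_internal
        next_internal += 1
        adj[u].remove(v)
        adj[v].remove(u)
        adj[u].append(mid)
        adj[v].append(mid)
        adj[mid] = [u, v, leaf]
        adj[leaf] = [mid]
        edges.remove((u, v))
        edges.extend([(u, mid), (v, mid), (mid, leaf)])

    def newick(node: int, parent: int) -> str:
        kids = [k for k in adj[node] if k != parent]
        if not kids:
            return f"{labels[node]}:1"
        return "(" + ",".join(newick(k, node) for k in kids) + "):1"

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 20 * n + 100))
    try:
        kids = ",".join(newick(k, center) for k in adj[center])
    finally:
        sys.setrecursionlimit(old)
    return read_newick(f"({kids});")


@dataclass
class ScenarioData:
    """One fully simulated scenario plus derived inputs for the pipeline."""

    spec: ScenarioSpec
    species_tree: dendropy.Tree
    truth: dict[str, tuple[str, ...]]
    gene_trees: list[dendropy.Tree]
    distances: DistanceMatrix  # average patristic over gene trees
    presence_absence: PresenceAbsenceMatrix
    pairs: PairSimilarityTable


def generate_scenario(
    spec: ScenarioSpec, noiseless_similarity: bool = False
) -> ScenarioData:
    """Simulate everything from one seed, in a fixed stage order."""
    rng = np.random.default_rng(spec.seed)
    species_tree, truth = simulate_species_tree(spec, rng)
    gene_trees = simulate_gene_trees(species_tree, spec, rng)
    distances = average_matrices([patristic_matrix(t) for t in gene_trees])
    pa = simulate_presence_absence(species_tree, spec, rng)
    pairs = simulate_pair_similarity(
        distances, spec, rng, noiseless=noiseless_similarity
    )
    return ScenarioData(spec, species_tree, truth, gene_trees, distances, pa, pairs)


def write_scenario(data: ScenarioData, out_dir: str | Path) -> RunManifest:
    """Write a scenario as plain-text pipeline inputs plus a manifest."""
    out = Path(out_dir)
    (out / "genetrees").mkdir(parents=True, exist_ok=True)
    _core.write_newick(data.species_tree, out / "species_tree.nwk")
    for i, tree in enumerate(data.gene_trees):
        _core.write_newick(tree, out / "genetrees" / f"gene{i + 1:04d}.nwk")
    data.presence_absence.write_tsv(out / "pa.tsv")
    data.pairs.write_tsv(out / "pairs.tsv")
    data.distances.write_tsv(out / "avg_dist.tsv")
    truth_lines = ["genome\tspecies"]
    for species, members in sorted(data.truth.items()):
        for g in members:
            truth_lines.append(f"{g}\t{species}")
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    manifest = RunManifest(seed=data.spec.seed, config=vars(data.spec).copy())
    for name in ("species_tree.nwk", "pa.tsv", "pairs.tsv", "avg_dist.tsv", "truth.tsv"):
        manifest.add_input(out / name)
    manifest.outputs = {"scenario_dir": str(out)}
    manifest.write(out / "manifest.json")
    return manifest
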