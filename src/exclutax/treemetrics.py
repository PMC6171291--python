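"""Tree-derived quantities.

Per-gene patristic (cophenetic) distance matrices and their genome-wide
average; squared correlation between gene-level matrices; unrooted
bipartitions and the Robinson-Foulds (RF) distance; the null distribution of
RF between independent uniformly random fully resolved trees; concordance
factors of clades across gene trees; and Fitch-parsimony gain/loss mapping
of gene presence/absence characters with ACCTRAN-style resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.special import gammaln, logsumexp

from .core import DistanceMatrix, PresenceAbsenceMatrix, leaf_labels, logger

__all__ = [
    "patristic_matrix",
    "average_matrices",
    "matrix_r2",
    "bipartitions",
    "robinson_foulds",
    "RFNull",
    "random_rf_null",
    "concordance_factor",
    "GainLossSummary",
    "fitch_gains_losses",
    "map_pan_genome",
]


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every pair of leaves.

    Single postorder accumulation: each node carries distances from the
    leaves beneath it; pairs across sibling subtrees are finalized when the
    subtrees meet.  O(n^2) overall.
    """
    labels = sorted(leaf_labels(tree))
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    # node -> (leaf indices below, distances from those leaves to the node)
    below: dict[dendropy.Node, tuple[list[int], list[float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = ([index[node.taxon.label]], [0.0])
            continue
        merged_idx: list[int] = []
        merged_d: list[float] = []
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above {child.taxon.label if child.is_leaf() else 'an internal node'}"
                )
            idx, dist = below.pop(child)
            dist = [d + child.edge.length for d in dist]
            for i, di in zip(merged_idx, merged_d):
                for j, dj in zip(idx, dist):
                    out[i, j] = out[j, i] = di + dj
            merged_idx.extend(idx)
            merged_d.extend(dist)
        below[node] = (merged_idx, merged_d)
    return DistanceMatrix(tuple(labels), out)


def average_matrices(matrices: Sequence[DistanceMatrix]) -> DistanceMatrix:
    """Entrywise arithmetic mean of label-aligned distance matrices."""
    if not matrices:
        raise ValueError("need at least one matrix to average")
    first = matrices[0]
    ref = set(first.labels)
    total = np.array(first.values, dtype=float, copy=True)
    for m in matrices[1:]:
        if set(m.labels) != ref:
            missing = sorted(ref ^ set(m.labels))
            raise ValueError(f"label sets differ between matrices: {missing}")
        total += m.align_to(first.labels).values
    return DistanceMatrix(first.labels, total / len(matrices))


def matrix_r2(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Squared Pearson correlation over the strict upper triangles.

    Returns NaN (with a warning) when either triangle has zero variance.
    """
    if set(a.labels) != set(b.labels):
        raise ValueError("matrices must share the same label set")
    if a.n < 3:
        raise ValueError("need at least 3 taxa for a correlation")
    x = a.condensed()
    y = b.align_to(a.labels).condensed()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("matrix_r2 undefined: zero variance in a triangle")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------------
# bipartitions and Robinson-Foulds
# ---------------------------------------------------------------------------


def _canonical_split(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def _split_masks(tree: dendropy.Tree, index: dict[str, int]) -> set[int]:
    """Non-trivial splits as canonical leaf bitmasks (min of mask, ~mask)."""
    n = len(index)
    full = (1 << n) - 1
    splits: set[int] = set()
    below: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = 1 << index[node.taxon.label]
        else:
            mask = 0
            for c in node.child_nodes():
                mask |= below.pop(id(c))
            below[id(node)] = mask
            if node.parent_node is not None and 2 <= mask.bit_count() <= n - 2:
                splits.add(min(mask, full ^ mask))
    return splits


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial unrooted bipartitions, one per internal edge.

    Each split is stored as its canonical side (the smaller side, or the
    lexicographically first side on ties).  Rooted trees are interpreted
    unrooted, so a binary root contributes a single split.
    """
    labels = sorted(leaf_labels(tree))
    all_leaves = frozenset(labels)
    index = {label: i for i, label in enumerate(labels)}
    out: set[frozenset[str]] = set()
    for mask in _split_masks(tree, index):
        side = frozenset(labels[i] for i in range(len(labels)) if mask >> i & 1)
        out.add(_canonical_split(side, all_leaves))
    return out


def robinson_foulds(a: dendropy.Tree, b: dendropy.Tree) -> int:
    """Symmetric-difference (RF) distance over non-trivial bipartitions."""
    leaves_a, leaves_b = set(leaf_labels(a)), set(leaf_labels(b))
    if leaves_a != leaves_b:
        raise ValueError(
            f"trees have different leaf sets: {sorted(leaves_a ^ leaves_b)}"
        )
    index = {label: i for i, label in enumerate(sorted(leaves_a))}
    return len(_split_masks(a, index) ^ _split_masks(b, index))


# ---------------------------------------------------------------------------
# RF null distribution for uniformly random trees
# ---------------------------------------------------------------------------


def _log_rooted_count(k: np.ndarray) -> np.ndarray:
    """log of the number of rooted binary trees on k labelled leaves.

    (2k-3)!! = (2k-2)! / (2^(k-1) (k-1)!), with the k=1 count equal to 1.
    """
    k = np.asarray(k, dtype=float)
    return gammaln(2 * k - 1) - (k - 1) * np.log(2.0) - gammaln(k)


@dataclass(frozen=True)
class RFNull:
    """Null distribution of RF between two independent uniform trees.

    ``expected_shared`` is the exact expected number of shared non-trivial
    splits (by linearity over splits, using double-factorial tree counts);
    the far tail of the shared-split count uses its Poisson limit with that
    exact mean, evaluated in log space.
    """

    n: int
    expected_shared: float

    @property
    def max_rf(self) -> int:
        return 2 * (self.n - 3)

    @property
    def expected_rf(self) -> float:
        return self.max_rf - 2.0 * self.expected_shared

    def log10_p_le(self, rf: float) -> float:
        """log10 P(RF <= rf) under the null."""
        s_min = int(np.ceil((self.max_rf - rf) / 2.0))
        if s_min <= 0:
            return 0.0
        lam = self.expected_shared
        ks = np.arange(s_min, s_min + 400)
        log_terms = -lam + ks * np.log(lam) - gammaln(ks + 1)
        return float(logsumexp(log_terms) / np.log(10.0))


def random_rf_null(n: int) -> RFNull:
    """RF null for two independent uniform fully resolved unrooted trees.

    E[shared splits] = (1/2) sum_{a=2}^{n-2} C(n,a) * p(a)^2 where p(a) is
    the probability that a uniform tree contains a fixed split with side
    sizes (a, n-a): p(a) = r(a) r(n-a) / b(n) for rooted counts r and the
    unrooted count b(n) = (2n-5)!!.
    """
    if n < 4:
        raise ValueError("RF null requires n >= 4")
    a = np.arange(2, n - 1)
    log_b = float(gammaln(2 * n - 4) - (n - 3) * np.log(2.0) - gammaln(n - 2))
    log_p = _log_rooted_count(a) + _log_rooted_count(n - a) - log_b
    log_choose = gammaln(n + 1) - gammaln(a + 1) - gammaln(n - a + 1)
    expected = 0.5 * float(np.exp(logsumexp(log_choose + 2 * log_p)))
    return RFNull(n=n, expected_shared=expected)


# ---------------------------------------------------------------------------
# concordance factors
# ---------------------------------------------------------------------------


def concordance_factor(
    group: Iterable[str], gene_trees: Sequence[dendropy.Tree]
) -> float:
    """Fraction of gene trees containing ``group`` as an unrooted split."""
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    group = frozenset(group)
    all_leaves = frozenset(leaf_labels(gene_trees[0]))
    if not group <= all_leaves:
        raise ValueError(f"labels outside the trees: {sorted(group - all_leaves)}")
    if not (2 <= len(group) <= len(all_leaves) - 2):
        raise ValueError("group corresponds to a trivial split")
    target = _canonical_split(group, all_leaves)
    hits = sum(1 for t in gene_trees if target in bipartitions(t))
    return hits / len(gene_trees)


# ---------------------------------------------------------------------------
# Fitch parsimony gain/loss mapping
# ---------------------------------------------------------------------------


@dataclass
class GainLossSummary:
    """Gain/loss counts from parsimony mapping of 0/1 characters on a tree."""

    gains: int
    losses: int
    branch_count: int
    per_branch_gains: dict[str, int] = field(default_factory=dict)
    per_branch_losses: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.gains + self.losses

    @property
    def gains_per_branch(self) -> float:
        return self.gains / self.branch_count

    @property
    def losses_per_branch(self) -> float:
        return self.losses / self.branch_count


def _tree_arrays(tree: dendropy.Tree):
    """Postorder node list, child index lists, and branch names.

    Branches are named by the sorted leaf set below them (';'-joined), which
    is stable across traversals.
    """
    nodes = list(tree.postorder_node_iter())
    pos = {id(node): i for i, node in enumerate(nodes)}
    children = [[pos[id(c)] for c in node.child_nodes()] for node in nodes]
    below: list[frozenset[str]] = [frozenset()] * len(nodes)
    for i, node in enumerate(nodes):
        if node.is_leaf():
            below[i] = frozenset((node.taxon.label,))
        else:
            below[i] = frozenset().union(*(below[j] for j in children[i]))
    names = [";".join(sorted(s)) for s in below]
    return nodes, children, below, names


def _fitch_acctran(
    leaf_states: np.ndarray,
    leaf_rows: list[int],
    children: list[list[int]],
    root_state: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Fitch bottom-up + ACCTRAN-style top-down over characters.

    ``leaf_states``: (n_leaves, n_chars) 0/1.  State sets are bitmasks
    (1 = {absent}, 2 = {present}, 3 = ambiguous); multifurcations use the
    intersection-if-nonempty-else-union generalization.  Ambiguity at the
    root resolves to ``root_state``; below the root a node keeps its parent's
    state whenever its Fitch set allows it, which pushes changes rootward.
    Returns (final states per node, gain flags per node, loss flags per node),
    each (n_nodes, n_chars).
    """
    n_nodes = len(children)
    n_chars = leaf_states.shape[1]
    sets = np.zeros((n_nodes, n_chars), dtype=np.uint8)
    row_of = {i: row for row, i in enumerate(leaf_rows)}
    for i, kids in enumerate(children):  # postorder: children before parents
        if not kids:
            sets[i] = np.where(leaf_states[row_of[i]] > 0, 2, 1)
            continue
        inter = np.full(n_chars, 3, dtype=np.uint8)
        union = np.zeros(n_chars, dtype=np.uint8)
        for k in kids:
            inter &= sets[k]
            union |= sets[k]
        sets[i] = np.where(inter != 0, inter, union)

    final = np.zeros((n_nodes, n_chars), dtype=np.uint8)  # 0/1 states
    gains = np.zeros((n_nodes, n_chars), dtype=bool)
    losses = np.zeros((n_nodes, n_chars), dtype=bool)
    root = n_nodes - 1  # postorder: root last
    root_mask = sets[root]
    final[root] = np.where(root_mask == 2, 1, np.where(root_mask == 1, 0, root_state))
    for i in range(n_nodes - 1, -1, -1):
        parent_state = final[i]
        for k in children[i]:
            parent_bit = np.left_shift(1, parent_state).astype(np.uint8)
            keep = (sets[k] & parent_bit) != 0
            child_state = np.where(keep, parent_state, 1 - parent_state)
            final[k] = child_state
            gains[k] = (parent_state == 0) & (child_state == 1)
            losses[k] = (parent_state == 1) & (child_state == 0)
    return final, gains, losses


def fitch_gains_losses(
    tree: dendropy.Tree,
    character: dict[str, int] | dict[str, bool],
    root_state: int = 0,
) -> GainLossSummary:
    """Minimum-change gain/loss mapping of one presence/absence character.

    The total equals the Fitch parsimony minimum.  Ambiguity at the root is
    resolved to ``root_state`` (default absent: auxiliary genes missing from
    the core are treated as ancestrally absent), and changes are placed as
    close to the root as the Fitch sets permit.
    """
    labels = leaf_labels(tree)
    missing = [l for l in labels if l not in character]
    if missing:
        raise ValueError(f"leaves without a character state: {missing}")
    nodes, children, below, names = _tree_arrays(tree)
    leaf_rows = [i for i, node in enumerate(nodes) if node.is_leaf()]
    states = np.array(
        [[1 if character[nodes[i].taxon.label] else 0] for i in leaf_rows],
        dtype=np.uint8,
    )
    _, gains, losses = _fitch_acctran(states, leaf_rows, children, root_state)
    branch_count = len(nodes) - 1
    per_g = {names[i]: int(gains[i, 0]) for i in range(len(nodes) - 1) if gains[i, 0]}
    per_l = {names[i]: int(losses[i, 0]) for i in range(len(nodes) - 1) if losses[i, 0]}
    return GainLossSummary(
        gains=int(gains[:-1].sum()),
        losses=int(losses[:-1].sum()),
        branch_count=branch_count,
        per_branch_gains=per_g,
        per_branch_losses=per_l,
    )


def map_pan_genome(
    tree: dendropy.Tree,
    matrix: PresenceAbsenceMatrix,
    root_state: int = 0,
    unrooted_branch_count: bool = True,
) -> GainLossSummary:
    """Sum Fitch/ACCTRAN gains and losses over all gene clusters.

    Clusters present in every genome contribute no changes.  Per-branch
    averages use the unrooted branch count 2n-3 for a fully resolved tree
    (the rooted tree's two root edges form one unrooted branch); set
    ``unrooted_branch_count=False`` to divide by the rooted edge count.
    """
    labels = leaf_labels(tree)
    if set(labels) != set(matrix.genomes):
        raise ValueError(
            f"tree leaves and matrix genomes differ: {sorted(set(labels) ^ set(matrix.genomes))}"
        )
    nodes, children, below, names = _tree_arrays(tree)
    leaf_rows = [i for i, node in enumerate(nodes) if node.is_leaf()]
    order = [matrix.genome_index(nodes[i].taxon.label) for i in leaf_rows]
    states = matrix.binary[order].astype(np.uint8)
    _, gains, losses = _fitch_acctran(states, leaf_rows, children, root_state)
    gains = gains[:-1]  # drop root (no branch above it)
    losses = losses[:-1]
    branch_count = len(nodes) - 1
    if unrooted_branch_count and len(tree.seed_node.child_nodes()) == 2:
        branch_count -= 1
    per_g = {names[i]: int(gains[i].sum()) for i in range(gains.shape[0])}
    per_l = {names[i]: int(losses[i].sum()) for i in range(losses.shape[0])}
    return GainLossSummary(
        gains=int(gains.sum()),
        losses=int(losses.sum()),
        branch_count=branch_count,
        per_branch_gains=per_g,
        per_branch_losses=per_l,
    )
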