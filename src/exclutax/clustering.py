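"""UPGMA tree construction and gene-content (Jaccard) distances.

UPGMA is used both for the pan-genome (gene-content) tree and for the tree
built from the genome-wide average patristic distances; it is the natural
choice here because every exclusive group of a distance matrix appears as a
clade of its UPGMA tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix, PresenceAbsenceMatrix

__all__ = ["MergeRecord", "MergeTrace", "upgma", "jaccard_matrix"]


@dataclass(frozen=True)
class MergeRecord:
    members_a: tuple[str, ...]
    members_b: tuple[str, ...]
    height: float


MergeTrace = list[MergeRecord]


def upgma(
    d: DistanceMatrix, weighted: bool = False
) -> tuple[dendropy.Tree, MergeTrace]:
    """Agglomerative average-linkage clustering into a rooted ultrametric tree.

    At each step the pair of clusters with the minimum average inter-cluster
    distance is merged at height d/2.  ``weighted=False`` (default) is classic
    UPGMA — the new cluster's distances are size-weighted averages — while
    ``weighted=True`` gives WPGMA's simple means.  Ties on the minimum
    distance are broken by the lexicographically smallest member label of the
    candidate pair (then the second label), so the result is independent of
    input order.  On an ultrametric input matrix the generating tree is
    reconstructed exactly.
    """
    n = d.n
    if n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    taxa = dendropy.TaxonNamespace(list(d.labels))
    work = np.array(d.values, dtype=float, copy=True)
    np.fill_diagonal(work, np.inf)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    heights = {i: 0.0 for i in range(n)}
    members: dict[int, tuple[str, ...]] = {
        i: (label,) for i, label in enumerate(d.labels)
    }
    nodes: dict[int, dendropy.Node] = {}
    for i, label in enumerate(d.labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[i] = node
    reps = {i: label for i, label in enumerate(d.labels)}  # smallest member label

    trace: MergeTrace = []
    next_id = n
    # `work` is padded as clusters are created; rows/cols of retired clusters
    # stay +inf so argmin never revisits them
    work = np.pad(work, ((0, n - 1), (0, n - 1)), constant_values=np.inf)
    for _ in range(n - 1):
        sub = work[np.ix_(active, active)]
        dmin = sub.min()
        pairs = []
        ai, aj = np.nonzero(sub == dmin)
        for x, y in zip(ai, aj):
            if x < y:
                i, j = active[x], active[y]
                la, lb = sorted((reps[i], reps[j]))
                pairs.append((la, lb, i, j))
        _, _, i, j = min(pairs)
        if reps[i] > reps[j]:  # canonical child order, independent of input order
            i, j = j, i
        height = dmin / 2.0

        parent = dendropy.Node()
        for child_id in (i, j):
            child = nodes[child_id]
            child.edge.length = height - heights[child_id]
            parent.add_child(child)
        nodes[next_id] = parent
        heights[next_id] = height
        sizes[next_id] = sizes[i] + sizes[j]
        members[next_id] = tuple(sorted(members[i] + members[j]))
        reps[next_id] = min(reps[i], reps[j])
        trace.append(MergeRecord(members[i], members[j], height))

        others = [k for k in active if k not in (i, j)]
        if weighted:
            new_d = (work[i, others] + work[j, others]) / 2.0
        else:
            new_d = (
                sizes[i] * work[i, others] + sizes[j] * work[j, others]
            ) / (sizes[i] + sizes[j])
        work[next_id, others] = new_d
        work[others, next_id] = new_d
        work[i, :] = work[:, i] = np.inf
        work[j, :] = work[:, j] = np.inf
        active = others + [next_id]
        next_id += 1

    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = nodes[next_id - 1]
    tree.is_rooted = True
    return tree, trace


def jaccard_matrix(matrix: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distance on binarized gene content.

    d(i, j) = 1 - |P_i intersect P_j| / |P_i union P_j| over presence sets;
    shared absences carry no signal.  Copy counts above 1 are binarized.
    """
    binary = matrix.binary
    empty = np.nonzero(~binary.any(axis=1))[0]
    if empty.size:
        bad = [matrix.genomes[i] for i in empty]
        raise ValueError(f"genome(s) with empty presence set: {bad}")
    values = squareform(pdist(binary, metric="jaccard"))
    return DistanceMatrix(matrix.genomes, values)
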