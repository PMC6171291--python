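"""Exclusivity scoring of genome groups under an average relatedness matrix.

A group is *exclusive* when all of its members are more closely related to
each other than any of them is to an outsider.  Quantitatively, for a group
G under distance matrix d:

    score(G) = min_{i in G, j not in G} d(i, j)  -  max_{i, k in G} d(i, k)

Positive score means exclusive; singletons are trivially exclusive.  Every
exclusive group of a distance matrix appears as a clade of its UPGMA tree,
which makes exhaustive enumeration tractable: build the UPGMA tree and score
its clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .clustering import jaccard_matrix, upgma
from .core import DistanceMatrix, PresenceAbsenceMatrix, leaf_labels, logger

__all__ = [
    "ExclusivityRecord",
    "exclusivity_score",
    "score_clades",
    "annotate_tree",
    "AnnotationSummary",
    "enumerate_exclusive_groups",
    "brute_force_exclusive_groups",
    "ExclusivityProfile",
    "depth_profile",
    "SubsampleCurve",
    "subsample_curve",
]


@dataclass(frozen=True)
class ExclusivityRecord:
    """Score of one leaf-label group: min out-group minus max in-group distance."""

    group: tuple[str, ...]
    max_in: float
    min_out: float
    score: float
    trivially_exclusive: bool = False

    def is_exclusive(self, slack: float = 0.0) -> bool:
        return self.score > -slack


def _score_indices(
    values: np.ndarray, idx: np.ndarray, out_idx: np.ndarray
) -> tuple[float, float]:
    max_in = float(values[np.ix_(idx, idx)].max()) if idx.size > 1 else 0.0
    min_out = float(values[np.ix_(idx, out_idx)].min())
    return max_in, min_out


def exclusivity_score(
    group: Iterable[str], d: DistanceMatrix, permissive: bool = False
) -> ExclusivityRecord:
    """Score one group against a distance matrix.

    The full label set has no outside and is unscorable: error by default,
    ``min_out = +inf`` in permissive mode.
    """
    group = tuple(sorted(set(group)))
    if not group:
        raise ValueError("group must be non-empty")
    pos = {label: i for i, label in enumerate(d.labels)}
    unknown = [g for g in group if g not in pos]
    if unknown:
        raise KeyError(f"labels absent from the matrix: {unknown}")
    idx = np.array([pos[g] for g in group])
    out_idx = np.array([i for label, i in pos.items() if label not in set(group)])
    if out_idx.size == 0:
        if not permissive:
            raise ValueError("group covers every label; no outside exists")
        max_in = float(d.values[np.ix_(idx, idx)].max()) if idx.size > 1 else 0.0
        return ExclusivityRecord(group, max_in, np.inf, np.inf, len(group) == 1)
    max_in, min_out = _score_indices(d.values, idx, out_idx)
    score = min_out - max_in
    return ExclusivityRecord(
        group, max_in, min_out, score, trivially_exclusive=(len(group) == 1 and score > 0)
    )


def _clades(tree: dendropy.Tree):
    """(node, leaf set) for every internal non-root node, preorder."""
    below: dict[int, tuple[str, ...]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = (node.taxon.label,)
        else:
            below[id(node)] = tuple(
                sorted(sum((below[id(c)] for c in node.child_nodes()), ()))
            )
    for node in tree.preorder_node_iter():
        if node.parent_node is not None and not node.is_leaf():
            yield node, below[id(node)]


def score_clades(
    tree: dendropy.Tree, d: DistanceMatrix
) -> list[tuple[dendropy.Node, ExclusivityRecord]]:
    """Score the leaf set below every internal non-root node of a tree."""
    labels = leaf_labels(tree)
    if set(labels) != set(d.labels):
        raise ValueError(
            f"tree leaves and matrix labels differ: {sorted(set(labels) ^ set(d.labels))}"
        )
    pos = {label: i for i, label in enumerate(d.labels)}
    all_idx = np.arange(d.n)
    out = []
    for node, group in _clades(tree):
        idx = np.array(sorted(pos[g] for g in group))
        mask = np.ones(d.n, dtype=bool)
        mask[idx] = False
        max_in, min_out = _score_indices(d.values, idx, all_idx[mask])
        out.append(
            (node, ExclusivityRecord(group, max_in, min_out, min_out - max_in))
        )
    return out


@dataclass
class AnnotationSummary:
    internal_edges: int
    exclusive_edges: int
    fraction_exclusive: float
    uncovered_leaves: tuple[str, ...]  # leaves in no non-trivial exclusive group


def annotate_tree(
    tree: dendropy.Tree, d: DistanceMatrix, slack: float = 0.0
) -> tuple[dendropy.Tree, AnnotationSummary]:
    """Attach exclusivity scores to every internal edge of ``tree``.

    Each internal non-root node receives the ``ExclusivityRecord`` of its
    subtended leaf set (on ``node.exclusivity``, with the score mirrored in
    the node label so newick output carries it).  The summary counts edges
    with score > -slack and lists leaves covered by no non-trivial exclusive
    group.
    """
    scored = score_clades(tree, d)
    covered: set[str] = set()
    n_exclusive = 0
    for node, rec in scored:
        node.exclusivity = rec
        node.label = f"{rec.score:.6g}"
        if rec.is_exclusive(slack):
            n_exclusive += 1
            covered.update(rec.group)
    uncovered = tuple(sorted(set(leaf_labels(tree)) - covered))
    n_edges = len(scored)
    summary = AnnotationSummary(
        internal_edges=n_edges,
        exclusive_edges=n_exclusive,
        fraction_exclusive=(n_exclusive / n_edges) if n_edges else 0.0,
        uncovered_leaves=uncovered,
    )
    return tree, summary


def enumerate_exclusive_groups(
    d: DistanceMatrix, slack: float = 0.0
) -> list[ExclusivityRecord]:
    """All exclusive groups of a matrix, via the clades of its UPGMA tree.

    Returns non-trivial clades with score > -slack plus every singleton
    (flagged trivially exclusive).  At slack 0 the non-trivial groups are
    exactly the exclusive subsets of the label set (UPGMA is guaranteed to
    contain every exclusive group as a clade).
    """
    records: list[ExclusivityRecord] = []
    if d.n >= 2:
        tree, _ = upgma(d)
        for _, rec in score_clades(tree, d):
            if rec.is_exclusive(slack):
                records.append(rec)
    for label in d.labels:
        records.append(exclusivity_score([label], d))
    records.sort(key=lambda r: (len(r.group), r.group))
    return records


def brute_force_exclusive_groups(d: DistanceMatrix) -> list[ExclusivityRecord]:
    """Score every non-empty proper subset; keep strictly positive scores.

    Exponential-time reference enumeration, guarded to n <= 15.
    """
    if d.n > 15:
        raise ValueError("brute force enumeration is guarded to n <= 15")
    labels = d.labels
    records = []
    for mask in range(1, (1 << d.n) - 1):
        idx = np.array([i for i in range(d.n) if mask >> i & 1])
        out_idx = np.array([i for i in range(d.n) if not mask >> i & 1])
        max_in, min_out = _score_indices(d.values, idx, out_idx)
        if min_out - max_in > 0:
            records.append(
                ExclusivityRecord(
                    tuple(labels[i] for i in idx),
                    max_in,
                    min_out,
                    min_out - max_in,
                    trivially_exclusive=(idx.size == 1),
                )
            )
    records.sort(key=lambda r: (len(r.group), r.group))
    return records


# ---------------------------------------------------------------------------
# clade-depth profile
# ---------------------------------------------------------------------------


@dataclass
class ExclusivityProfile:
    """Exclusivity versus clade depth (max in-group distance), binned."""

    depths: np.ndarray
    scores: np.ndarray
    bin_edges: np.ndarray
    bin_means: np.ndarray
    bin_sds: np.ndarray  # NaN where a bin holds fewer than 2 points
    bin_counts: np.ndarray


def depth_profile(
    records: Sequence[ExclusivityRecord], bins: int = 25
) -> ExclusivityProfile:
    """Bin clade exclusivity scores by clade depth (max in-group distance)."""
    nontrivial = [r for r in records if len(r.group) >= 2]
    if not nontrivial:
        raise ValueError("no non-trivial records to profile")
    depths = np.array([r.max_in for r in nontrivial])
    scores = np.array([r.score for r in nontrivial])
    lo, hi = depths.min(), depths.max()
    if hi == lo:
        edges = np.array([lo, lo + 1.0])
        bins = 1
    else:
        edges = np.linspace(lo, hi, bins + 1)
    which = np.clip(np.searchsorted(edges, depths, side="right") - 1, 0, bins - 1)
    means = np.full(bins, np.nan)
    sds = np.full(bins, np.nan)
    counts = np.zeros(bins, dtype=int)
    for b in range(bins):
        sel = scores[which == b]
        counts[b] = sel.size
        if sel.size:
            means[b] = sel.mean()
        if sel.size >= 2:
            sds[b] = sel.std(ddof=1)
    return ExclusivityProfile(depths, scores, edges, means, sds, counts)


# ---------------------------------------------------------------------------
# genome-subsampling robustness
# ---------------------------------------------------------------------------


@dataclass
class SubsampleCurve:
    """Exclusivity of re-computed pan-trees on random genome subsamples.

    For each sample size and replicate, genomes are drawn without
    replacement, a gene-content UPGMA tree is rebuilt on the subsample, and
    its clades are scored against the corresponding rows/columns of the
    *original* average-distance matrix.
    """

    sizes: tuple[int, ...]
    replicates: int
    seed: int
    prop_exclusive: np.ndarray  # (n_sizes, replicates)
    mean_score: np.ndarray  # (n_sizes, replicates)
    groups: list[list[list[ExclusivityRecord]]] = field(repr=False, default=None)

    @property
    def prop_mean(self) -> np.ndarray:
        return self.prop_exclusive.mean(axis=1)

    @property
    def prop_sd(self) -> np.ndarray:
        return self.prop_exclusive.std(axis=1, ddof=1)

    @property
    def score_mean(self) -> np.ndarray:
        return np.nanmean(self.mean_score, axis=1)

    @property
    def score_sd(self) -> np.ndarray:
        return np.nanstd(self.mean_score, axis=1, ddof=1)


def subsample_curve(
    d_full: DistanceMatrix,
    pa: PresenceAbsenceMatrix,
    sizes: Sequence[int],
    replicates: int = 25,
    seed: int = 0,
) -> SubsampleCurve:
    """Robustness of exclusivity to genome sampling depth."""
    if set(d_full.labels) != set(pa.genomes):
        raise ValueError("distance matrix and presence/absence genomes differ")
    n = d_full.n
    if any(s > n for s in sizes):
        raise ValueError("subsample size exceeds the number of genomes")
    if any(s < 4 for s in sizes):
        logger.warning("subsample sizes below 4 yield few or no scorable clades")
    rng = np.random.default_rng(seed)
    genomes = np.array(pa.genomes)
    props = np.zeros((len(sizes), replicates))
    means = np.zeros((len(sizes), replicates))
    all_groups: list[list[list[ExclusivityRecord]]] = []
    for si, size in enumerate(sizes):
        size_groups = []
        for rep in range(replicates):
            chosen = sorted(rng.choice(n, size=size, replace=False))
            sub_labels = [str(g) for g in genomes[chosen]]
            pa_sub = pa.subset_genomes(sub_labels)
            d_sub = d_full.submatrix(sub_labels)
            tree, _ = upgma(jaccard_matrix(pa_sub))
            scored = [rec for _, rec in score_clades(tree, d_sub)]
            size_groups.append(scored)
            if scored:
                scores = np.array([r.score for r in scored])
                props[si, rep] = float((scores > 0).mean())
                means[si, rep] = float(scores.mean())
            else:
                props[si, rep] = np.nan
                means[si, rep] = np.nan
        all_groups.append(size_groups)
    return SubsampleCurve(
        sizes=tuple(int(s) for s in sizes),
        replicates=replicates,
        seed=seed,
        prop_exclusive=props,
        mean_score=means,
        groups=all_groups,
    )
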