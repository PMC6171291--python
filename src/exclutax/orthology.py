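"""Construction of clusters of orthologous genes (COGs) from protein hits.

Pipeline: filter pairwise protein hits (E-value, HSSP distance, match-length
fraction), connect reciprocal best hits between genomes into a homology
graph, require a minimum global amino-acid identity on each edge, cluster
the graph with Markov clustering (MCL), and assemble the genome x cluster
copy-count matrix with its core/pan partition.  Helper steps for the
concatenated core-gene alignment (representative-gene choice, gap-column
trimming) live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.sparse.csgraph import connected_components

from .core import AnalysisConfig, PresenceAbsenceMatrix, logger

__all__ = [
    "hssp_distance",
    "global_identity",
    "filter_hits",
    "reciprocal_best_hits",
    "CogClustering",
    "mcl_cluster",
    "assemble_matrix",
    "CompletenessReport",
    "completeness_filter",
    "CorePanPartition",
    "core_pan_partition",
    "choose_representative",
    "trim_alignment_columns",
]


def hssp_distance(percent_identity: float, alignment_length: int) -> float:
    """Percent identity minus the length-dependent homology threshold curve.

    The threshold curve is 480 * L^(-0.32 * (1 + exp(-L/1000))) for alignment
    lengths 11 < L <= 450 and the constant 19.5 beyond 450 residues; the two
    regimes are continuous to within 0.1.  Undefined at L <= 11.
    """
    if alignment_length <= 11:
        raise ValueError("HSSP curve is undefined for alignment length <= 11")
    if not (0.0 <= percent_identity <= 100.0):
        raise ValueError("percent identity must lie in [0, 100]")
    if alignment_length > 450:
        return percent_identity - 19.5
    L = float(alignment_length)
    return percent_identity - 480.0 * L ** (-0.32 * (1.0 + math.exp(-L / 1000.0)))


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def global_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical columns over an end-to-end protein alignment.

    Alignment by dynamic programming with BLOSUM62 and affine gap penalties
    (open 11, extend 1); identity = identical columns / total alignment
    columns, including gapped columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def _hit_lengths(
    hits: pd.DataFrame, seq_lengths: Mapping[str, int] | None
) -> tuple[pd.Series, pd.Series] | None:
    if "qlen" in hits.columns and "slen" in hits.columns:
        return hits["qlen"], hits["slen"]
    if seq_lengths is not None:
        missing = sorted(
            set(hits["qseqid"]).union(hits["sseqid"]) - set(seq_lengths)
        )
        if missing:
            raise ValueError(f"no sequence length for id(s): {missing[:5]}")
        return (
            hits["qseqid"].map(seq_lengths),
            hits["sseqid"].map(seq_lengths),
        )
    return None


def filter_hits(
    hits: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    seq_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Retain hits passing the E-value, HSSP and match-length-fraction tests.

    A hit survives iff E-value <= evalue_max, HSSP distance >= hssp_min
    (alignments of <= 11 residues fail outright), and the local alignment
    covers at least match_len_frac_min of the shorter sequence (configurable
    to the longer).  The global-identity requirement is applied later, after
    reciprocal-best-hit pairing.  Filtering is idempotent.
    """
    cfg = cfg or AnalysisConfig()
    keep = hits["evalue"] <= cfg.evalue_max
    lengths = hits["length"].to_numpy()
    hssp = np.full(len(hits), -np.inf)
    ok = lengths > 11
    pid = hits["pident"].to_numpy()
    short = np.minimum(lengths[ok], 450.0)
    curve = 480.0 * short ** (-0.32 * (1.0 + np.exp(-short / 1000.0)))
    curve = np.where(lengths[ok] > 450, 19.5, curve)
    hssp[ok] = pid[ok] - curve
    keep &= hssp >= cfg.hssp_min
    pair = _hit_lengths(hits, seq_lengths)
    if pair is None:
        raise ValueError(
            "match-length-fraction test needs qlen/slen columns or a sequence "
            "length mapping"
        )
    qlen, slen = pair
    if cfg.match_len_denominator == "shorter":
        denom = np.minimum(qlen.to_numpy(), slen.to_numpy())
    else:
        denom = np.maximum(qlen.to_numpy(), slen.to_numpy())
    keep &= lengths >= cfg.match_len_frac_min * denom
    return hits.loc[keep].reset_index(drop=True)


def reciprocal_best_hits(
    hits: pd.DataFrame,
    cfg: AnalysisConfig | None = None,
    sequences: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Connect proteins whose best hits in each other's genomes are mutual.

    For each (query protein, target genome) the best hit is chosen by bit
    score, ties broken by lower E-value then lexicographically smallest
    subject id — a total order, so the graph is invariant to input record
    order.  An edge is created only when both directions choose each other,
    the two proteins come from different genomes, and the pair passes the
    global-identity threshold: computed by global alignment when sequences
    are supplied, otherwise approximated as pident * length / max(qlen, slen)
    when lengths are available (flagged in the log), otherwise skipped with a
    warning.  Edge weight = mean of the two directional bit scores.
    """
    cfg = cfg or AnalysisConfig()
    best: dict[tuple[str, str], tuple[float, float, str, float, object]] = {}
    for row in hits.itertuples(index=False):
        if row.qseqid == row.sseqid or row.qgenome == row.sgenome:
            continue
        key = (row.qseqid, row.sgenome)
        # larger bitscore, then smaller evalue, then smaller subject id
        cand = (-row.bitscore, row.evalue, row.sseqid, row.bitscore, row)
        if key not in best or cand < best[key]:
            best[key] = cand
    graph = nx.Graph()
    genome_of = {}
    for row in hits.itertuples(index=False):
        genome_of[row.qseqid] = row.qgenome
        genome_of[row.sseqid] = row.sgenome
    approx_used = False
    for (q, sg), (_, _, s, bitscore, row) in sorted(best.items()):
        if q >= s:
            continue  # handle each unordered pair once, from the smaller id
        back = best.get((s, genome_of[q]))
        if back is None or back[2] != q:
            continue
        if sequences is not None:
            ident = global_identity(sequences[q], sequences[s])
        elif hasattr(row, "qlen"):
            ident = row.pident * row.length / max(row.qlen, row.slen)
            approx_used = True
        else:
            ident = None
        if ident is not None and ident < cfg.global_identity_min:
            continue
        weight = (bitscore + back[3]) / 2.0
        graph.add_node(q, genome=genome_of[q])
        graph.add_node(s, genome=genome_of[s])
        graph.add_edge(q, s, weight=float(weight))
    if approx_used:
        logger.info(
            "global identity approximated from local hits (pident * length / "
            "max(qlen, slen)); supply sequences for exact values"
        )
    if sequences is None and not any(
        hasattr(r, "qlen") for r in hits.head(1).itertuples(index=False)
    ):
        logger.warning("no sequences or lengths available; global-identity test skipped")
    return graph


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------


@dataclass
class CogClustering:
    """Assignment of proteins to gene clusters (COGs)."""

    protein_to_cluster: dict[str, str]
    members: dict[str, tuple[str, ...]]
    genome_of: dict[str, str]
    converged: bool = True

    def copy_counts(self) -> dict[str, dict[str, int]]:
        """cluster id -> genome -> copy count."""
        out: dict[str, dict[str, int]] = {}
        for cluster, prots in self.members.items():
            counts: dict[str, int] = {}
            for p in prots:
                g = self.genome_of[p]
                counts[g] = counts.get(g, 0) + 1
            out[cluster] = counts
        return out

    def to_tsv(self) -> str:
        lines = ["protein\tcluster"]
        for p in sorted(self.protein_to_cluster):
            lines.append(f"{p}\t{self.protein_to_cluster[p]}")
        return "\n".join(lines) + "\n"


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 1.8,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> CogClustering:
    """Markov clustering of the homology graph.

    Column-normalizes the weighted adjacency with self-loops (weight = the
    node's maximum incident edge weight, 1 for isolated nodes), then
    alternates expansion (matrix square) and inflation (entrywise power,
    renormalize) until the maximum entry change drops below ``tol`` or
    ``max_iter`` iterations (warn and emit the current clustering).
    Clusters are the connected components of the converged support, so
    vertices in different input components are never merged.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return CogClustering({}, {}, {})
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w <= 0:
            raise ValueError("edge weights must be positive")
        M[index[u], index[v]] = w
        M[index[v], index[u]] = w
    loop = M.max(axis=0)
    loop[loop == 0] = 1.0
    M[np.diag_indices(n)] = loop
    M /= M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M
        M = M ** inflation
        M[M < 1e-12] = 0.0
        M /= M.sum(axis=0, keepdims=True)
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; emitting current state", max_iter)

    support = (M > 1e-6) | (M.T > 1e-6)
    n_comp, assignment = connected_components(support, directed=False)
    groups: dict[int, list[str]] = {}
    for v, comp in zip(nodes, assignment):
        groups.setdefault(int(comp), []).append(v)
    ordered = sorted(groups.values(), key=lambda g: g[0])
    width = max(5, len(str(len(ordered))))
    protein_to_cluster: dict[str, str] = {}
    members: dict[str, tuple[str, ...]] = {}
    for i, group in enumerate(ordered):
        cid = f"COG{i + 1:0{width}d}"
        members[cid] = tuple(sorted(group))
        for p in group:
            protein_to_cluster[p] = cid
    genome_of = {v: graph.nodes[v].get("genome") for v in nodes}
    return CogClustering(protein_to_cluster, members, genome_of, converged)


def assemble_matrix(
    clustering: CogClustering, genomes: Sequence[str]
) -> tuple[PresenceAbsenceMatrix, float]:
    """Genome x cluster copy-count matrix plus the single-copy fraction.

    The fraction is over cluster-genome incidences (cells with count >= 1).
    Genomes with no clustered protein keep a row of zeros (they fall to the
    completeness filter later) with a warning.
    """
    if any(g is None for g in clustering.genome_of.values()):
        raise ValueError("every protein needs a genome assignment")
    genomes = tuple(genomes)
    clusters = tuple(sorted(clustering.members))
    counts = np.zeros((len(genomes), len(clusters)), dtype=np.int64)
    gpos = {g: i for i, g in enumerate(genomes)}
    for ci, cid in enumerate(clusters):
        for p in clustering.members[cid]:
            g = clustering.genome_of[p]
            if g not in gpos:
                raise ValueError(f"protein {p!r} maps to unknown genome {g!r}")
            counts[gpos[g], ci] += 1
    empty = [g for g, i in gpos.items() if counts[i].sum() == 0]
    if empty:
        logger.warning("genome(s) with zero clustered proteins: %s", empty)
    incidences = counts[counts > 0]
    single_copy_fraction = float((incidences == 1).mean()) if incidences.size else 1.0
    return PresenceAbsenceMatrix(genomes, clusters, counts), single_copy_fraction


@dataclass
class CompletenessReport:
    reference_core_size: int
    required_count: int
    per_genome: dict[str, int]
    dropped: tuple[str, ...]


def completeness_filter(
    matrix: PresenceAbsenceMatrix,
    complete_genomes: Sequence[str],
    min_fraction: float = 0.957,
) -> tuple[PresenceAbsenceMatrix, CompletenessReport]:
    """Drop genomes missing too much of the complete genomes' shared core.

    The reference core is the set of clusters present in every genome listed
    in ``complete_genomes``; a genome is retained when it possesses at least
    ceil(min_fraction * |reference core|) of those clusters.  Genomes in
    ``complete_genomes`` are never dropped when min_fraction <= 1.
    """
    complete = tuple(complete_genomes)
    if not complete:
        raise ValueError("complete_genomes must be non-empty")
    rows = [matrix.genome_index(g) for g in complete]
    binary = matrix.binary
    ref_core = binary[rows].all(axis=0)
    core_size = int(ref_core.sum())
    if core_size == 0:
        raise ValueError("reference core is empty: complete genomes share no cluster")
    required = math.ceil(min_fraction * core_size)
    tally = binary[:, ref_core].sum(axis=1)
    keep = tally >= required
    kept = [g for g, k in zip(matrix.genomes, keep) if k]
    dropped = tuple(g for g, k in zip(matrix.genomes, keep) if not k)
    report = CompletenessReport(
        reference_core_size=core_size,
        required_count=required,
        per_genome={g: int(t) for g, t in zip(matrix.genomes, tally)},
        dropped=dropped,
    )
    return matrix.subset_genomes(kept), report


@dataclass
class CorePanPartition:
    core: tuple[str, ...]  # present in every genome
    pan: tuple[str, ...]  # present in >= 2 genomes (includes the core)
    genome_unique: tuple[str, ...]  # present in exactly 1 genome


def core_pan_partition(matrix: PresenceAbsenceMatrix) -> CorePanPartition:
    """Split clusters into core (all genomes) and pan (>= 2 genomes).

    Clusters found in a single genome belong to neither and are reported
    separately.
    """
    if not matrix.clusters:
        raise ValueError("empty presence/absence matrix")
    presence = matrix.binary.sum(axis=0)
    n = len(matrix.genomes)
    clusters = np.array(matrix.clusters)
    return CorePanPartition(
        core=tuple(clusters[presence == n]),
        pan=tuple(clusters[presence >= 2]),
        genome_unique=tuple(clusters[presence == 1]),
    )


def choose_representative(
    candidates: Sequence[tuple[str, str]],
    peers: Sequence[str],
) -> str:
    """Pick one gene copy to represent a genome inside a cluster.

    Lexicographic criteria: (i) fewest degenerate positions (Ns), (ii) lowest
    average p-distance to the cluster's other genes (p = 1 - global identity
    / 100), (iii) length closest to the median length of the cluster's genes;
    remaining ties go to the smallest gene id.
    """
    if not candidates:
        raise ValueError("need at least one candidate gene")
    if len(candidates) == 1:
        return candidates[0][0]
    median_len = float(np.median([len(s) for s in peers])) if peers else 0.0

    def key(item: tuple[str, str]):
        gene_id, seq = item
        n_count = seq.upper().count("N")
        if peers:
            dist = float(
                np.mean([1.0 - global_identity(seq, p) / 100.0 for p in peers])
            )
        else:
            dist = 0.0
        return (n_count, dist, abs(len(seq) - median_len), gene_id)

    return min(candidates, key=key)[0]


def trim_alignment_columns(
    alignment: Sequence[tuple[str, str]], max_gap_fraction: float = 0.90
) -> list[tuple[str, str]]:
    """Drop alignment columns whose gap fraction strictly exceeds the cutoff.

    ``alignment`` is a sequence of (id, aligned sequence) rows of equal
    length; gaps are '-' or '.'.  Row order is preserved.
    """
    if not alignment:
        return []
    lengths = {len(seq) for _, seq in alignment}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: rows have unequal lengths")
    rows = np.array([list(seq) for _, seq in alignment])
    gaps = (rows == "-") | (rows == ".")
    keep = gaps.mean(axis=0) <= max_gap_fraction
    return [
        (name, "".join(row[keep])) for (name, _), row in zip(alignment, rows)
    ]
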