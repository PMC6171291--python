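"""Shared domain types, file I/O, configuration and logging.

The package works with five carriers: phylogenetic trees (dendropy ``Tree``
objects, read and written as newick), labelled symmetric distance matrices,
genome x gene-cluster presence/absence (copy count) matrices, protein hit
tables (BLAST tabular style) and pairwise genome similarity tables (ANI/AF).
Every reader validates the invariants the downstream analyses rely on.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "logger",
    "configure_logging",
    "AnalysisConfig",
    "DistanceMatrix",
    "PresenceAbsenceMatrix",
    "read_hit_table",
    "PairSimilarityTable",
    "read_pair_similarity",
    "read_newick",
    "write_newick",
    "validate_tree",
    "RunManifest",
]

logger = logging.getLogger("exclutax")

#: significant digits used when serializing distances
FLOAT_DIGITS = 10
#: absolute tolerance for symmetry / ultrametricity checks on read
SYMMETRY_TOL = 1e-9


def configure_logging(level: str = "info") -> None:
    """Send package log records to standard error at the given level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s exclutax: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Thresholds and switches for the full analysis.

    Defaults are the conventional values for prokaryote genome collections:
    hit filtering at E <= 1e-3, HSSP distance >= 20 and >= 30% match length;
    60% global amino-acid identity for homology; MCL inflation 1.8; genome
    completeness at 95.7% of the reference core; species-level similarity at
    ANI >= 96.5% and AF >= 0.60.
    """

    evalue_max: float = 1e-3
    hssp_min: float = 20.0
    match_len_frac_min: float = 0.30
    match_len_denominator: str = "shorter"  # or "longer"
    global_identity_min: float = 60.0
    mcl_inflation: float = 1.8
    core_fraction_min: float = 0.957
    gap_col_max: float = 0.90
    ani_min: float = 96.5
    af_min: float = 0.60
    exclusivity_slack: float = 0.0
    linkage: str = "single"  # or "complete"
    ani_symmetrize: str = "mean"  # or "min"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.match_len_frac_min <= 1.0):
            raise ValueError("match_len_frac_min must lie in [0, 1]")
        if self.match_len_denominator not in ("shorter", "longer"):
            raise ValueError("match_len_denominator must be 'shorter' or 'longer'")
        if not (0.0 <= self.global_identity_min <= 100.0):
            raise ValueError("global_identity_min must lie in [0, 100]")
        if self.mcl_inflation <= 1.0:
            raise ValueError("mcl_inflation must exceed 1")
        if not (0.0 < self.core_fraction_min <= 1.0):
            raise ValueError("core_fraction_min must lie in (0, 1]")
        if not (0.0 <= self.gap_col_max <= 1.0):
            raise ValueError("gap_col_max must lie in [0, 1]")
        if not (0.0 <= self.ani_min <= 100.0):
            raise ValueError("ani_min must lie in [0, 100]")
        if not (0.0 <= self.af_min <= 1.0):
            raise ValueError("af_min must lie in [0, 1]")
        if self.linkage not in ("single", "single_literal", "complete"):
            raise ValueError(
                "linkage must be 'single', 'single_literal' or 'complete'"
            )
        if self.ani_symmetrize not in ("mean", "min"):
            raise ValueError("ani_symmetrize must be 'mean' or 'min'")
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be nonnegative")

    _FLOAT_FIELDS = (
        "evalue_max",
        "hssp_min",
        "match_len_frac_min",
        "global_identity_min",
        "mcl_inflation",
        "core_fraction_min",
        "gap_col_max",
        "ani_min",
        "af_min",
        "exclusivity_slack",
    )

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def from_text(cls, text: str) -> "AnalysisConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"config line {lineno}: expected 'key = value'")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"config line {lineno}: unknown key {key!r}")
            if key in cls._FLOAT_FIELDS:
                kwargs[key] = float(value)
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_text(Path(path).read_text())

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if values.shape != (n, n):
            raise ValueError(
                f"matrix shape {values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("distance matrix entries must be finite")
        if np.any(values < -SYMMETRY_TOL):
            raise ValueError("distance matrix entries must be nonnegative")
        if np.abs(values - values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("distance matrix is asymmetric beyond tolerance 1e-9")
        if n and np.abs(np.diag(values)).max() > SYMMETRY_TOL:
            raise ValueError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown label {label!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index(a), self.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(label) for label in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def align_to(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Reorder to the given label sequence (must be a permutation)."""
        if set(labels) != set(self.labels) or len(labels) != self.n:
            raise ValueError("align_to requires a permutation of the labels")
        return self.submatrix(labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("\t".join(("",) + self.labels) + "\n")
        for i, label in enumerate(self.labels):
            row = "\t".join(f"{v:.{FLOAT_DIGITS}g}" for v in self.values[i])
            buf.write(f"{label}\t{row}\n")
        return buf.getvalue()

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def _read_distance_tsv(text: str) -> DistanceMatrix:
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    labels = tuple(str(c) for c in df.columns)
    row_labels = tuple(str(r) for r in df.index)
    if labels != row_labels:
        raise ValueError("distance TSV row labels differ from column labels")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def _read_distance_phylip(text: str) -> DistanceMatrix:
    lines = [line for line in text.splitlines() if line.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    rows: list[list[float]] = []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if len(labels) != n:
        raise ValueError(f"PHYLIP matrix announces {n} taxa, found {len(labels)}")
    return DistanceMatrix(tuple(labels), np.asarray(rows, dtype=float))


def read_distance_matrix(source: str | Path) -> DistanceMatrix:
    """Read a distance matrix from TSV-with-header or square PHYLIP text.

    ``source`` may be a path or the raw text itself.  The dialect is sniffed
    from the first line: a leading integer count means PHYLIP.
    """
    text = _as_text(source)
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if first.split() and first.split()[0].isdigit():
        return _read_distance_phylip(text)
    return _read_distance_tsv(text)


def _as_text(source: str | Path) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str) and "\n" not in source and len(source) < 4096:
        try:
            if Path(source).is_file():
                return Path(source).read_text()
        except OSError:
            pass
    return str(source)


# ---------------------------------------------------------------------------
# presence/absence matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Genomes x gene clusters copy-count matrix (0 = absent)."""

    genomes: tuple[str, ...]
    clusters: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise ValueError("presence/absence counts must be integers")
            counts = as_int
        object.__setattr__(self, "counts", counts)
        if counts.shape != (len(self.genomes), len(self.clusters)):
            raise ValueError("counts shape does not match genome/cluster labels")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("genome labels must be unique")
        if len(set(self.clusters)) != len(self.clusters):
            raise ValueError("cluster labels must be unique")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def binary(self) -> np.ndarray:
        return self.counts > 0

    def genome_index(self, genome: str) -> int:
        try:
            return self.genomes.index(genome)
        except ValueError:
            raise KeyError(f"unknown genome {genome!r}") from None

    def subset_genomes(self, genomes: Sequence[str]) -> "PresenceAbsenceMatrix":
        idx = [self.genome_index(g) for g in genomes]
        return PresenceAbsenceMatrix(tuple(genomes), self.clusters, self.counts[idx])

    def subset_clusters(self, clusters: Sequence[str]) -> "PresenceAbsenceMatrix":
        pos = {c: i for i, c in enumerate(self.clusters)}
        idx = [pos[c] for c in clusters]
        return PresenceAbsenceMatrix(self.genomes, tuple(clusters), self.counts[:, idx])

    def to_tsv(self) -> str:
        df = pd.DataFrame(self.counts, index=list(self.genomes), columns=list(self.clusters))
        return df.to_csv(sep="\t", index_label="genome")

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def read_presence_absence(source: str | Path) -> PresenceAbsenceMatrix:
    """Read a genomes x clusters count TSV (first column = genome labels)."""
    df = pd.read_csv(io.StringIO(_as_text(source)), sep="\t", index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("presence/absence matrix contains non-numeric entries")
    as_int = values.astype(np.int64)
    if not np.array_equal(as_int, values):
        raise ValueError("presence/absence counts must be integers")
    if as_int.size and as_int.min() < 0:
        raise ValueError("presence/absence counts must be nonnegative")
    return PresenceAbsenceMatrix(
        tuple(str(g) for g in df.index), tuple(str(c) for c in df.columns), as_int
    )


# ---------------------------------------------------------------------------
# protein hit tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_hit_table(
    source: str | Path,
    genome_of: Mapping[str, str] | Callable[[str], str] | None = None,
) -> pd.DataFrame:
    """Read a 12- or 14-column BLAST tabular (outfmt 6) hit table.

    Columns 13-14, when present, are the query and subject sequence lengths.
    Every sequence id must map to its genome of origin: either pass a mapping
    or a callable, or use ids of the form ``genome|protein`` (the default
    split on the first ``|``).
    """
    df = pd.read_csv(io.StringIO(_as_text(source)), sep="\t", header=None, comment="#")
    if df.shape[1] == 12:
        df.columns = HIT_COLUMNS
    elif df.shape[1] == 14:
        df.columns = HIT_COLUMNS + ["qlen", "slen"]
    else:
        raise ValueError(f"hit table must have 12 or 14 columns, found {df.shape[1]}")
    df["qseqid"] = df["qseqid"].astype(str)
    df["sseqid"] = df["sseqid"].astype(str)
    if genome_of is None:
        genome_fn = _genome_from_id
    elif callable(genome_of):
        genome_fn = genome_of
    else:
        mapping = dict(genome_of)

        def genome_fn(seq_id: str) -> str:
            try:
                return mapping[seq_id]
            except KeyError:
                raise ValueError(f"no genome assignment for sequence id {seq_id!r}")

    df["qgenome"] = df["qseqid"].map(genome_fn)
    df["sgenome"] = df["sseqid"].map(genome_fn)
    validate_hit_table(df)
    return df


def _genome_from_id(seq_id: str) -> str:
    if "|" not in seq_id:
        raise ValueError(
            f"sequence id {seq_id!r} has no 'genome|protein' structure and no "
            "genome mapping was provided"
        )
    return seq_id.split("|", 1)[0]


def validate_hit_table(df: pd.DataFrame) -> None:
    if ((df["pident"] < 0) | (df["pident"] > 100)).any():
        raise ValueError("percent identity must lie in [0, 100]")
    if (df["length"] < 1).any():
        raise ValueError("alignment length must be positive")
    if (df["evalue"] < 0).any():
        raise ValueError("E-values must be nonnegative")
    if df["qgenome"].isna().any() or df["sgenome"].isna().any():
        raise ValueError("every sequence id needs a genome assignment")


# ---------------------------------------------------------------------------
# pairwise genome similarity (ANI / AF)
# ---------------------------------------------------------------------------


@dataclass
class PairSimilarityTable:
    """One ANI/AF record per unordered genome pair, after symmetrization."""

    records: pd.DataFrame  # columns: genome_a, genome_b, ani, af

    def __post_init__(self) -> None:
        df = self.records
        required = {"genome_a", "genome_b", "ani", "af"}
        if not required.issubset(df.columns):
            raise ValueError(f"records need columns {sorted(required)}")
        swapped = df["genome_a"] > df["genome_b"]
        if swapped.any():
            df = df.copy()
            a = df.loc[swapped, "genome_b"].to_numpy()
            df.loc[swapped, "genome_b"] = df.loc[swapped, "genome_a"].to_numpy()
            df.loc[swapped, "genome_a"] = a
            self.records = df
        keys = list(zip(df["genome_a"], df["genome_b"]))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate unordered genome pair in similarity table")
        if ((df["ani"] < 0) | (df["ani"] > 100)).any():
            raise ValueError("ANI must lie in [0, 100]")
        if ((df["af"] < 0) | (df["af"] > 1)).any():
            raise ValueError("AF must lie in [0, 1]")
        self._lookup = {
            key: (float(ani), float(af))
            for key, ani, af in zip(keys, df["ani"], df["af"])
        }

    def genomes(self) -> set[str]:
        return set(self.records["genome_a"]) | set(self.records["genome_b"])

    def get(self, a: str, b: str) -> tuple[float, float] | None:
        """(ANI, AF) for the unordered pair, or None if absent."""
        if a == b:
            return (100.0, 1.0)
        key = (a, b) if a <= b else (b, a)
        return self._lookup.get(key)

    def to_tsv(self) -> str:
        return self.records.to_csv(sep="\t", index=False)

    def write_tsv(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def read_pair_similarity(
    source: str | Path, symmetrize: str = "mean"
) -> PairSimilarityTable:
    """Read a directional genome-pair similarity TSV and symmetrize it.

    Expected columns (with or without header): genome_a, genome_b, ani, af.
    Tools report two directed rows per pair; the two directions are combined
    by ``symmetrize``: "mean" (default) or "min".  Pairs reported in a single
    direction are retained with a warning.
    """
    if symmetrize not in ("mean", "min"):
        raise ValueError("symmetrize must be 'mean' or 'min'")
    text = _as_text(source)
    first = text.splitlines()[0] if text.strip() else ""
    header = 0 if any(tok.lower() in ("ani", "af") for tok in first.split("\t")) else None
    df = pd.read_csv(io.StringIO(text), sep="\t", header=header)
    if df.shape[1] < 4:
        raise ValueError("pair similarity table needs 4 columns: a, b, ANI, AF")
    df = df.iloc[:, :4]
    df.columns = ["genome_a", "genome_b", "ani", "af"]
    df["genome_a"] = df["genome_a"].astype(str)
    df["genome_b"] = df["genome_b"].astype(str)
    if ((df["ani"] < 0) | (df["ani"] > 100)).any():
        raise ValueError("ANI must lie in [0, 100]")
    if ((df["af"] < 0) | (df["af"] > 1)).any():
        raise ValueError("AF must lie in [0, 1]")
    if (df["genome_a"] == df["genome_b"]).any():
        raise ValueError("self pairs are not allowed in the similarity table")

    seen_directed: set[tuple[str, str]] = set()
    grouped: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for a, b, ani, af in df.itertuples(index=False):
        if (a, b) in seen_directed:
            raise ValueError(f"duplicate directed record for pair ({a}, {b})")
        seen_directed.add((a, b))
        key = (a, b) if a <= b else (b, a)
        grouped.setdefault(key, []).append((float(ani), float(af)))
    rows = []
    n_single = 0
    for (a, b), vals in grouped.items():
        if len(vals) > 2:
            raise ValueError(f"more than two directed records for pair ({a}, {b})")
        if len(vals) == 1:
            n_single += 1
            ani, af = vals[0]
        else:
            anis, afs = zip(*vals)
            agg = np.mean if symmetrize == "mean" else min
            ani, af = float(agg(anis)), float(agg(afs))
        rows.append((a, b, ani, af))
    if n_single:
        logger.warning(
            "%d genome pair(s) present in a single direction only; using that "
            "direction as-is",
            n_single,
        )
    out = pd.DataFrame(rows, columns=["genome_a", "genome_b", "ani", "af"])
    out = out.sort_values(["genome_a", "genome_b"], ignore_index=True)
    return PairSimilarityTable(out)


# ---------------------------------------------------------------------------
# trees (newick via dendropy)
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse one newick tree; validates leaf-label uniqueness and lengths."""
    text = _as_text(source)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    validate_tree(tree)
    return tree


def validate_tree(tree: dendropy.Tree) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(label is None for label in labels):
        raise ValueError("every leaf must carry a label")
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf label(s): {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length on edge to {edge.head_node}")


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{FLOAT_DIGITS}g",
    )
    if path is not None:
        Path(path).write_text(text)
    return text


def leaf_labels(tree: dendropy.Tree) -> tuple[str, ...]:
    return tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Machine-readable record of a run: inputs, config, seed, outputs."""

    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    config: dict = field(default_factory=dict)
    seed: int = 0
    version: str = "0.1.0"
    outputs: dict[str, str] = field(default_factory=dict)  # stage -> path

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.inputs[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        tmp.replace(path)  # atomic on POSIX
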