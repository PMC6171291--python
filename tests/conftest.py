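"""Shared fixtures and independent oracle helpers for the test suite.

The oracles here are deliberately naive — exhaustive enumeration, direct
path-walking, brute-force minimization — and never reuse the code paths
they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import exclutax as ex
from exclutax.core import DistanceMatrix


# ---------------------------------------------------------------------------
# random inputs
# ---------------------------------------------------------------------------


def random_distance_matrix(n: int, rng: np.random.Generator) -> DistanceMatrix:
    """Random symmetric matrix with distinct positive off-diagonal entries."""
    vals = rng.uniform(0.5, 10.0, size=(n, n))
    vals = (vals + vals.T) / 2.0
    np.fill_diagonal(vals, 0.0)
    labels = tuple(f"t{i:02d}" for i in range(n))
    return DistanceMatrix(labels, vals)


def random_rooted_tree(labels, rng: np.random.Generator, with_lengths=True):
    """Random rooted binary tree over the labels (random joins), as newick."""
    parts = [f"{l}:{rng.uniform(0.1, 2.0):.6f}" if with_lengths else l for l in labels]
    parts = list(parts)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        merged = f"({a},{b})"
        if with_lengths:
            merged += f":{rng.uniform(0.1, 2.0):.6f}"
        parts.append(merged)
    newick = parts[0]
    if with_lengths:  # strip the root edge length
        newick = newick[: newick.rfind(":")]
    return ex.read_newick(newick + ";")


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def all_rooted_topologies(labels: tuple[str, ...]):
    """Every labelled rooted binary topology over the labels, as newick."""
    if len(labels) == 1:
        yield labels[0]
        return
    rest = labels[1:]
    first = labels[0]
    for k in range(0, len(rest)):
        for left_rest in itertools.combinations(rest, k):
            left = (first,) + left_rest
            right = tuple(l for l in rest if l not in left_rest)
            if not right:
                continue
            for lt in all_rooted_topologies(left):
                for rt in all_rooted_topologies(right):
                    yield f"({lt},{rt})"


def all_unrooted_topologies(labels: tuple[str, ...]):
    """Every labelled unrooted binary topology, as rooted-at-first-leaf newick.

    A rooted binary tree on labels[1:] corresponds one-to-one to an unrooted
    tree on all labels with labels[0] attached at its root.
    """
    for sub in all_rooted_topologies(labels[1:]):
        yield f"({labels[0]},{sub});"


def brute_force_min_changes(tree, character: dict[str, int]) -> int:
    """Minimum state changes over all ancestral 0/1 labelings (exhaustive)."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for assignment in itertools.product((0, 1), repeat=len(internal)):
        state = {id(n): s for n, s in zip(internal, assignment)}
        for n in nodes:
            if n.is_leaf():
                state[id(n)] = int(character[n.taxon.label])
        changes = sum(
            1
            for n in nodes
            if n.parent_node is not None and state[id(n)] != state[id(n.parent_node)]
        )
        best = changes if best is None else min(best, changes)
    return best


def naive_patristic(tree) -> dict[tuple[str, str], float]:
    """All-pairs path-walk distances via parent chains."""
    leaves = list(tree.leaf_node_iter())
    out = {}

    def path_to_root(node):
        chain = []
        total = 0.0
        while node.parent_node is not None:
            chain.append((node, total))
            total += node.edge.length
            node = node.parent_node
        chain.append((node, total))
        return chain

    for a, b in itertools.combinations(leaves, 2):
        pa = {id(n): d for n, d in path_to_root(a)}
        for node, db in path_to_root(b):
            if id(node) in pa:
                da = pa[id(node)]
                key = tuple(sorted((a.taxon.label, b.taxon.label)))
                out[key] = da + db
                break
    return out


# ---------------------------------------------------------------------------
# session-scoped simulated scenarios (expensive, reused across tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def clean_scenario():
    """Zero-transfer, zero-rate-noise, zero-similarity-noise scenario."""
    spec = ex.ScenarioSpec(
        transfer_mean=0.0,
        rate_sigma=0.0,
        ani_noise_sd=0.0,
        af_noise_sd=0.0,
        seed=11,
    )
    return ex.generate_scenario(spec, noiseless_similarity=True)


@pytest.fixture(scope="session")
def default_scenario():
    """Default study conditions (calibrated transfer rate, noise on)."""
    return ex.generate_scenario(ex.ScenarioSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
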