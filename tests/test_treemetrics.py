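"""Patristic distances, RF and its null distribution, concordance, Fitch."""

import itertools

import dendropy
import numpy as np
import pytest

import exclutax as ex
from exclutax.core import DistanceMatrix
from exclutax.treemetrics import random_rf_null

from conftest import (
    all_unrooted_topologies,
    brute_force_min_changes,
    naive_patristic,
    random_rooted_tree,
)


class TestPatristic:
    def test_two_leaves(self):
        d = ex.patristic_matrix(ex.read_newick("(A:1,B:2);"))
        assert d.get("A", "B") == 3.0

    def test_balanced_quartet_by_hand(self):
        d = ex.patristic_matrix(ex.read_newick("((A:1,B:1):2,(C:1,D:1):2);"))
        assert d.get("A", "C") == 6.0
        assert d.get("A", "B") == 2.0

    def test_against_path_walk_oracle(self, rng):
        for _ in range(50):
            labels = [f"L{i}" for i in range(int(rng.integers(4, 15)))]
            tree = random_rooted_tree(labels, rng)
            d = ex.patristic_matrix(tree)
            for (a, b), expected in naive_patristic(tree).items():
                assert d.get(a, b) == pytest.approx(expected, abs=1e-9)

    def test_four_point_condition(self, rng):
        """Patristic matrices of additive trees satisfy the four-point condition."""
        for _ in range(20):
            labels = [f"L{i}" for i in range(8)]
            d = ex.patristic_matrix(random_rooted_tree(labels, rng))
            for quad in itertools.combinations(labels, 4):
                i, j, k, l = quad
                sums = sorted(
                    [
                        d.get(i, j) + d.get(k, l),
                        d.get(i, k) + d.get(j, l),
                        d.get(i, l) + d.get(j, k),
                    ]
                )
                assert sums[1] == pytest.approx(sums[2], abs=1e-8)

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            ex.patristic_matrix(ex.read_newick("((A:1,B:1),C:3);"))


class TestAverageMatrices:
    def test_idempotent_on_identical(self, rng):
        from conftest import random_distance_matrix

        m = random_distance_matrix(5, rng)
        avg = ex.average_matrices([m, m, m])
        np.testing.assert_allclose(avg.values, m.values)

    def test_simple_mean(self):
        a = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        b = DistanceMatrix(("A", "B"), np.array([[0.0, 4.0], [4.0, 0.0]]))
        assert ex.average_matrices([a, b]).get("A", "B") == 3.0

    def test_label_permutation_invariance(self, rng):
        from conftest import random_distance_matrix

        m1 = random_distance_matrix(6, rng)
        m2 = random_distance_matrix(6, rng)
        perm = list(rng.permutation(m2.labels))
        direct = ex.average_matrices([m1, m2])
        shuffled = ex.average_matrices([m1, m2.submatrix(perm)])
        np.testing.assert_allclose(direct.values, shuffled.values, atol=1e-12)

    def test_label_mismatch_rejected(self):
        a = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        b = DistanceMatrix(("A", "C"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="label"):
            ex.average_matrices([a, b])


class TestMatrixR2:
    def test_self_correlation(self, rng):
        from conftest import random_distance_matrix

        m = random_distance_matrix(5, rng)
        assert ex.matrix_r2(m, m) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        from conftest import random_distance_matrix

        m = random_distance_matrix(5, rng)
        vals = 2.0 * m.values + 1.0
        np.fill_diagonal(vals, 0.0)
        b = DistanceMatrix(m.labels, vals)
        assert ex.matrix_r2(m, b) == pytest.approx(1.0)

    def test_small_matrix_vs_direct_formula(self):
        a = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]], dtype=float
            ),
        )
        b = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 2, 1, 5], [2, 0, 3, 4], [1, 3, 0, 7], [5, 4, 7, 0]], dtype=float
            ),
        )
        x, y = a.condensed(), b.condensed()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert ex.matrix_r2(a, b) == pytest.approx(r * r, abs=1e-12)

    def test_zero_variance_returns_nan(self):
        flat = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        )
        other = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        )
        assert np.isnan(ex.matrix_r2(flat, other))


class TestBipartitions:
    def test_quartet_single_split(self):
        splits = ex.bipartitions(ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);"))
        assert splits == {frozenset({"A", "B"})} or splits == {frozenset({"C", "D"})}

    def test_caterpillar_count(self):
        tree = ex.read_newick("((((A:1,B:1):1,C:1):1,D:1):1,E:1);")
        assert len(ex.bipartitions(tree)) == 2  # n - 3

    def test_edge_cut_oracle(self, rng):
        for _ in range(25):
            labels = [f"L{i}" for i in range(int(rng.integers(4, 10)))]
            tree = random_rooted_tree(labels, rng)
            got = ex.bipartitions(tree)
            # oracle: clip each internal edge, split the leaf set
            expected = set()
            all_leaves = frozenset(labels)
            for node in tree.postorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(side) <= len(labels) - 2:
                    other = all_leaves - side
                    if len(side) < len(other) or (
                        len(side) == len(other)
                        and tuple(sorted(side)) < tuple(sorted(other))
                    ):
                        expected.add(side)
                    else:
                        expected.add(other)
            assert got == expected


class TestRobinsonFoulds:
    def test_identity(self, rng):
        tree = random_rooted_tree([f"L{i}" for i in range(8)], rng)
        assert ex.robinson_foulds(tree, tree) == 0

    def test_five_leaf_difference_by_hand(self):
        a = ex.read_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        b = ex.read_newick("((A:1,C:1):1,B:1,(D:1,E:1):1);")
        assert ex.robinson_foulds(a, b) == 2

    def test_maximum_attained_by_disjoint_caterpillars(self):
        """Interleaved caterpillar leaf orders share no split: RF = 2(n-3)."""
        n = 701
        labels = [f"t{i:03d}" for i in range(n)]

        def caterpillar(order):
            newick = f"({order[0]}:1,{order[1]}:1)"
            for label in order[2:]:
                newick = f"({newick}:1,{label}:1)"
            return ex.read_newick(newick + ";")

        a = caterpillar(labels)
        b = caterpillar(labels[0::2] + labels[1::2])
        assert ex.robinson_foulds(a, b) == 2 * (n - 3) == 1396

    def test_against_dendropy_oracle(self, rng):
        for _ in range(20):
            labels = [f"L{i}" for i in range(int(rng.integers(5, 12)))]
            t1 = random_rooted_tree(labels, rng)
            t2 = random_rooted_tree(labels, rng)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=ex.write_newick(t1), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=ex.write_newick(t2), schema="newick", taxon_namespace=ns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            from dendropy.calculate import treecompare

            expected = treecompare.symmetric_difference(d1, d2)
            assert ex.robinson_foulds(t1, t2) == expected

    def test_metric_axioms_spot_check(self, rng):
        labels = [f"L{i}" for i in range(8)]
        for _ in range(10):
            a = random_rooted_tree(labels, rng)
            b = random_rooted_tree(labels, rng)
            c = random_rooted_tree(labels, rng)
            assert ex.robinson_foulds(a, b) == ex.robinson_foulds(b, a)
            assert ex.robinson_foulds(a, c) <= (
                ex.robinson_foulds(a, b) + ex.robinson_foulds(b, c)
            )

    def test_leaf_mismatch_rejected(self, rng):
        a = random_rooted_tree(["A", "B", "C", "D"], rng)
        b = random_rooted_tree(["A", "B", "C", "E"], rng)
        with pytest.raises(ValueError, match="leaf"):
            ex.robinson_foulds(a, b)


class TestRFNull:
    def test_quartet_expectation_exact(self):
        # two uniform quartets agree with probability 1/3: E[RF] = 2 - 2/3
        assert random_rf_null(4).expected_rf == pytest.approx(4.0 / 3.0, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 6])
    def test_expectation_matches_exhaustive_enumeration(self, n):
        labels = tuple(f"t{i}" for i in range(n))
        trees = [ex.read_newick(t) for t in all_unrooted_topologies(labels)]
        splits = [ex.bipartitions(t) for t in trees]
        counts = {3: None, 5: 15, 6: 105}
        assert len(trees) == counts[n]
        rfs = [
            len(sa ^ sb) for sa in splits for sb in splits
        ]  # all ordered topology pairs, uniform model
        assert random_rf_null(n).expected_rf == pytest.approx(
            np.mean(rfs), abs=1e-9
        )

    @pytest.mark.parametrize("n", [10, 20])
    def test_expectation_matches_monte_carlo(self, n):
        rng = np.random.default_rng(100 + n)
        labels = [f"t{i}" for i in range(n)]
        rfs = np.array(
            [
                ex.robinson_foulds(
                    ex.random_topology(labels, rng), ex.random_topology(labels, rng)
                )
                for _ in range(10_000)
            ]
        )
        se = rfs.std(ddof=1) / np.sqrt(rfs.size)
        assert abs(rfs.mean() - random_rf_null(n).expected_rf) <= 3 * se

    def test_large_tree_values_match_published_scale(self):
        null = random_rf_null(701)
        assert round(null.expected_rf) == 1396
        # probability of two random 701-leaf trees being as close as RF=598
        log10p = null.log10_p_le(598)
        assert -1300 < log10p < -1150  # order of magnitude 10^-1230

    def test_tail_is_monotone_and_bounded(self):
        null = random_rf_null(30)
        values = [null.log10_p_le(x) for x in (10, 20, 30, 40, null.max_rf)]
        assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))
        assert null.log10_p_le(null.max_rf) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            random_rf_null(3)


class TestConcordance:
    def test_universal_clade(self, rng):
        labels = ["A", "B", "C", "D", "E"]
        trees = [ex.read_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")] * 4
        assert ex.concordance_factor({"A", "B"}, trees) == 1.0

    def test_absent_clade(self):
        trees = [ex.read_newick("(((A:1,B:1):1,C:1):1,(D:1,E:1):1);")] * 3
        assert ex.concordance_factor({"A", "C"}, trees) == 0.0

    def test_half_concordant(self):
        with_ab = ex.read_newick("(((A:1,B:1):1,C:1):1,D:1);")
        without = ex.read_newick("(((A:1,C:1):1,B:1):1,D:1);")
        assert ex.concordance_factor({"A", "B"}, [with_ab, without] * 2) == 0.5

    def test_strict_consensus_clades_fully_concordant(self, rng):
        """Any clade shared by every gene tree has concordance factor 1."""
        labels = [f"L{i}" for i in range(8)]
        trees = [random_rooted_tree(labels, rng) for _ in range(6)]
        shared = set.intersection(*(ex.bipartitions(t) for t in trees))
        for clade in shared:
            assert ex.concordance_factor(clade, trees) == 1.0

    def test_trivial_group_rejected(self):
        trees = [ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")]
        with pytest.raises(ValueError, match="trivial"):
            ex.concordance_factor({"A"}, trees)


class TestFitch:
    def test_all_present_no_changes(self):
        tree = ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = ex.fitch_gains_losses(tree, {l: 1 for l in "ABCD"})
        assert (s.gains, s.losses) == (0, 0)

    def test_single_clade_gain(self):
        tree = ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = ex.fitch_gains_losses(tree, {"A": 1, "B": 1, "C": 0, "D": 0})
        assert (s.gains, s.losses) == (1, 0)

    def test_discordant_character_two_gains_root_absent(self):
        tree = ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = ex.fitch_gains_losses(tree, {"A": 1, "B": 0, "C": 1, "D": 0})
        assert (s.gains, s.losses) == (2, 0)
        assert s.total == brute_force_min_changes(tree, {"A": 1, "B": 0, "C": 1, "D": 0})

    def test_root_present_convention_flips_to_losses(self):
        tree = ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        s = ex.fitch_gains_losses(
            tree, {"A": 1, "B": 0, "C": 1, "D": 0}, root_state=1
        )
        assert s.total == 2
        assert s.losses == 2

    def test_exhaustive_oracle_all_small_topologies(self):
        """Fitch total equals brute-force minimum on every 4- and 5-leaf tree."""
        from conftest import all_rooted_topologies

        for labels in (("A", "B", "C", "D"), ("A", "B", "C", "D", "E")):
            for topo in all_rooted_topologies(labels):
                tree = ex.read_newick(topo + ";")
                for bits in itertools.product((0, 1), repeat=len(labels)):
                    char = dict(zip(labels, bits))
                    s = ex.fitch_gains_losses(tree, char)
                    assert s.total == brute_force_min_changes(tree, char)
                    assert s.gains + s.losses == s.total

    def test_sampled_oracle_larger_trees(self, rng):
        for n in (6, 7, 8):
            labels = [f"L{i}" for i in range(n)]
            for _ in range(15):
                tree = random_rooted_tree(labels, rng)
                bits = rng.integers(0, 2, size=n)
                char = dict(zip(labels, (int(b) for b in bits)))
                s = ex.fitch_gains_losses(tree, char)
                assert s.total == brute_force_min_changes(tree, char)

    def test_missing_leaf_state_rejected(self):
        tree = ex.read_newick("((A:1,B:1):1,C:1);")
        with pytest.raises(ValueError, match="without"):
            ex.fitch_gains_losses(tree, {"A": 1, "B": 0})


class TestMapPanGenome:
    @staticmethod
    def quartet():
        return ex.read_newick("((A:1,B:1):1,(C:1,D:1):1);")

    def test_all_present_matrix_no_changes(self):
        pa = ex.PresenceAbsenceMatrix(
            ("A", "B", "C", "D"), ("c1", "c2"), np.ones((4, 2), dtype=int)
        )
        s = ex.map_pan_genome(self.quartet(), pa)
        assert (s.gains, s.losses) == (0, 0)

    def test_single_leaf_cluster_single_gain(self):
        pa = ex.PresenceAbsenceMatrix(
            ("A", "B", "C", "D"), ("c1",), np.array([[1], [0], [0], [0]])
        )
        s = ex.map_pan_genome(self.quartet(), pa)
        assert (s.gains, s.losses) == (1, 0)

    def test_branch_count_is_unrooted_edge_count(self):
        pa = ex.PresenceAbsenceMatrix(
            ("A", "B", "C", "D"), ("c1",), np.array([[1], [0], [0], [0]])
        )
        s = ex.map_pan_genome(self.quartet(), pa)
        assert s.branch_count == 2 * 4 - 3

    def test_matches_per_character_sum(self, rng):
        labels = [f"L{i}" for i in range(7)]
        tree = random_rooted_tree(labels, rng)
        counts = rng.integers(0, 2, size=(7, 20))
        pa = ex.PresenceAbsenceMatrix(
            tuple(labels), tuple(f"c{i}" for i in range(20)), counts
        )
        keep = [i for i in range(20) if counts[:, i].any()]
        pa = pa.subset_clusters([f"c{i}" for i in keep])
        s = ex.map_pan_genome(tree, pa)
        gains = losses = 0
        for c in pa.clusters:
            ci = pa.clusters.index(c)
            char = {l: int(pa.counts[i, ci]) for i, l in enumerate(pa.genomes)}
            per = ex.fitch_gains_losses(tree, char)
            gains += per.gains
            losses += per.losses
        assert (s.gains, s.losses) == (gains, losses)

    def test_published_totals_give_printed_per_branch_averages(self):
        # with 1,399 branches, the printed parsimony totals round to the
        # printed per-branch averages
        assert round(850208 / 1399) == 608
        assert round(263624 / 1399) == 188
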