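"""Tree model, Newick I/O, monophyly, rooting, NJ and tree-sample utilities."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mitoscreen.trees import (
    Bipartition,
    DistanceMatrix,
    LabelledTree,
    NewickParseError,
    chains_converged,
    is_monophyletic,
    majority_rule_consensus,
    mrca,
    neighbor_joining,
    pairwise_distance,
    parse_newick,
    root_with_outgroup,
    split_maxdiff,
    write_newick,
)
from mitoscreen.simulate import random_tree

from conftest import bruteforce_monophyletic, leaf_distance_matrix


class TestNewick:
    def test_two_leaf_tree(self):
        t = parse_newick("(A:1,B:2);")
        assert sorted(t.leaf_labels) == ["A", "B"]
        assert t.total_branch_length() == pytest.approx(3.0)

    def test_support_annotation_preserved(self):
        t = parse_newick("((A:1,B:1)0.99:0.5,C:2);")
        internal = [n for n in t.preorder() if not n.is_leaf and n.parent is not None]
        assert internal[0].support == pytest.approx(0.99)
        assert "0.99" in write_newick(t)

    def test_missing_lengths_default_zero(self):
        t = parse_newick("((A,B),C);")
        assert t.total_branch_length() == 0.0

    @pytest.mark.parametrize(
        "bad", ["(A,B)", "(A,,B);", "((A,B);", "(A:x,B:1);", "(A,B); junk"]
    )
    def test_malformed_raises_with_offset(self, bad):
        with pytest.raises(NewickParseError) as err:
            parse_newick(bad)
        assert err.value.offset >= 0
        assert "character" in str(err.value)

    def test_roundtrip_isomorphism_random_trees(self, rng):
        for i in range(100):
            n = int(rng.integers(4, 15))
            labels = [f"T{j}" for j in range(n)]
            t = random_tree(labels, rng)
            back = parse_newick(write_newick(t))
            assert back.bipartitions() == t.bipartitions()
            assert back.total_branch_length() == pytest.approx(
                t.total_branch_length(), rel=1e-6
            )


class TestMonophyly:
    def test_trivial_sets(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert is_monophyletic(t, {"A", "B", "C", "D"})
        assert is_monophyletic(t, {"A"})

    def test_unrooted_split_absent(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
        assert not is_monophyletic(t, {"A", "C"})
        assert is_monophyletic(t, {"A", "B"})

    def test_unknown_label_errors(self):
        t = parse_newick("(A:1,B:1);")
        with pytest.raises(KeyError):
            is_monophyletic(t, {"Z"})

    def test_matches_bipartition_enumeration_oracle(self, rng):
        """Exhaustive edge-removal oracle over random trees and leafsets."""
        for i in range(60):
            n = int(rng.integers(4, 13))
            t = random_tree([f"T{j}" for j in range(n)], rng,
                            rooted=bool(i % 2))
            labels = t.leaf_labels
            for _ in range(15):
                k = int(rng.integers(1, n + 1))
                ls = frozenset(rng.choice(labels, size=k, replace=False).tolist())
                assert is_monophyletic(t, ls) == bruteforce_monophyletic(t, ls), (
                    write_newick(t),
                    sorted(ls),
                )


class TestMrca:
    def test_single_leaf_is_itself(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert mrca(t, {"A"}).label == "A"

    def test_all_leaves_is_root(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert mrca(t, {"A", "B", "C", "D"}) is t.root

    def test_cherry_parent(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        node = mrca(t, {"A", "B"})
        assert sorted(c.label for c in node.children) == ["A", "B"]

    def test_unrooted_errors(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="root"):
            mrca(t, {"A", "B"})


class TestRooting:
    def test_single_outgroup_bisects_pendant(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:2):1);", rooted=False)
        r = root_with_outgroup(t, {"D"})
        assert r.rooted
        kids = r.root.children
        assert {k.length for k in kids} == {1.0}  # D's branch split 1+1

    def test_conflicting_outgroup_errors(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);", rooted=False)
        with pytest.raises(ValueError, match="bipartition"):
            root_with_outgroup(t, {"A", "C"})

    def test_total_length_conserved(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 12))
            t = random_tree([f"T{j}" for j in range(n)], rng, rooted=False)
            r = root_with_outgroup(t, {"T0"})
            assert r.total_branch_length() == pytest.approx(
                t.total_branch_length(), abs=1e-12
            )

    def test_path_lengths_conserved(self, rng):
        t = random_tree([f"T{j}" for j in range(8)], rng, rooted=False)
        r = root_with_outgroup(t, {"T3"})
        assert leaf_distance_matrix(r) == pytest.approx(leaf_distance_matrix(t))


class TestDistances:
    def test_identical_sequences(self):
        dm = pairwise_distance({"a": "ACDEF", "b": "ACDEF"}, model="p")
        assert dm[("a", "b")] == 0.0

    def test_p_distance(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAT"}, model="p")
        assert dm[("a", "b")] == pytest.approx(0.25)

    def test_poisson_correction(self):
        dm = pairwise_distance({"a": "AAAA", "b": "AAAT"}, model="poisson")
        assert dm[("a", "b")] == pytest.approx(-math.log(0.75), abs=1e-4)

    def test_pairwise_deletion(self):
        dm = pairwise_distance({"a": "A-AA", "b": "ATAT"}, model="p")
        assert dm[("a", "b")] == pytest.approx(1 / 3)

    def test_no_comparable_columns_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distance({"a": "A--", "b": "-TT"}, model="p")

    def test_saturated_poisson_errors(self):
        with pytest.raises(ValueError, match="saturated"):
            pairwise_distance({"a": "AAAA", "b": "TTTT"}, model="poisson")


class TestNeighborJoining:
    def test_three_taxon_lengths(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0.0]])
        )
        t = neighbor_joining(dm)
        lengths = {leaf.label: leaf.length for leaf in t.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 2.0})

    def test_additive_four_taxon(self):
        # distances from ((A:1,B:2):1,(C:1,D:1))
        d = np.array(
            [[0, 3, 3, 3], [3, 0, 4, 4], [3, 4, 0, 2], [3, 4, 2, 0.0]]
        )
        t = neighbor_joining(DistanceMatrix(("A", "B", "C", "D"), d))
        assert Bipartition.of({"A", "B"}, {"C", "D"}) in t.bipartitions()
        assert t.total_branch_length() == pytest.approx(6.0, abs=1e-9)

    def test_zero_matrix_star(self):
        t = neighbor_joining(DistanceMatrix(("A", "B", "C"), np.zeros((3, 3))))
        assert t.total_branch_length() == 0.0
        assert len(t.root.children) == 3

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("A", "B"), np.array([[0, 1], [2, 0.0]]))

    def test_additive_recovery_random_trees(self, rng):
        """Exact topology and length recovery from additive matrices."""
        for _ in range(25):
            n = int(rng.integers(4, 21))
            labels = [f"T{j}" for j in range(n)]
            true = random_tree(labels, rng, rooted=False)
            for leaf in true.leaves():  # keep lengths well away from zero
                leaf.length += 0.1
            dm_dict = leaf_distance_matrix(true)
            mat = np.zeros((n, n))
            order = sorted(labels)
            for i, a in enumerate(order):
                for j, b in enumerate(order):
                    if i < j:
                        mat[i, j] = mat[j, i] = dm_dict[(a, b)]
            est = neighbor_joining(DistanceMatrix(tuple(order), mat))
            assert est.bipartitions() == true.bipartitions()
            est_d = leaf_distance_matrix(est)
            for pair, d in dm_dict.items():
                assert est_d[pair] == pytest.approx(d, abs=1e-9)

    def test_matches_dendropy(self, rng):
        """Cross-check against an independent NJ implementation."""
        dendropy = pytest.importorskip("dendropy")
        n = 8
        labels = [f"T{j}" for j in range(n)]
        mat = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.5, 2.0, size=len(iu[0]))
        mat[iu] = vals
        mat = mat + mat.T
        ours = neighbor_joining(DistanceMatrix(tuple(labels), mat))
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(f"{x:.10f}" for x in mat[i]) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv)
        )
        theirs = pdm.nj_tree()
        their_splits = set()
        all_names = frozenset(labels)
        for edge in theirs.preorder_edge_iter():
            head = edge.head_node
            below = frozenset(
                lf.taxon.label for lf in head.leaf_iter()
            )
            if 1 < len(below) < n - 1:
                their_splits.add(Bipartition.of(below, all_names - below))
        assert {bp for bp in ours.bipartitions()} == their_splits


class TestConsensus:
    def test_identical_trees_full_support(self):
        trees = [parse_newick("((A:1,B:1):1,(C:1,D:1):1);") for _ in range(4)]
        cons = majority_rule_consensus(trees, burnin_fraction=0.0)
        bps = cons.bipartitions()
        assert bps == trees[0].bipartitions()
        supports = [
            n.support for n in cons.preorder() if not n.is_leaf and n.parent is not None
        ]
        assert all(s == pytest.approx(1.0) for s in supports)

    def test_conflicting_trees_give_star(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        cons = majority_rule_consensus([a, b], burnin_fraction=0.0)
        assert cons.bipartitions() == set()

    def test_two_of_three_majority(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,B),(C,D));")
        c = parse_newick("((A,C),(B,D));")
        cons = majority_rule_consensus([a, b, c], burnin_fraction=0.0)
        (bp,) = cons.bipartitions()
        assert bp == Bipartition.of({"A", "B"}, {"C", "D"})
        node = [
            n for n in cons.preorder() if not n.is_leaf and n.parent is not None
        ][0]
        assert node.support == pytest.approx(2 / 3)

    def test_burnin_discards_prefix(self):
        early = [parse_newick("((A,C),(B,D));")] * 2
        late = [parse_newick("((A,B),(C,D));")] * 6
        cons = majority_rule_consensus(early + late, burnin_fraction=0.25)
        assert Bipartition.of({"A", "B"}, {"C", "D"}) in cons.bipartitions()

    def test_mismatched_leafsets_error(self):
        with pytest.raises(ValueError, match="leaf set"):
            majority_rule_consensus(
                [parse_newick("(A,B,C);"), parse_newick("(A,B,D);")]
            )

    def test_consensus_splits_compatible_and_majority(self, rng):
        trees = [random_tree([f"T{j}" for j in range(8)], rng) for _ in range(9)]
        cons = majority_rule_consensus(trees, burnin_fraction=0.0)
        bps = list(cons.bipartitions())
        for i in range(len(bps)):
            for j in range(i + 1, len(bps)):
                assert bps[i].compatible_with(bps[j])
        for node in cons.preorder():
            if not node.is_leaf and node.parent is not None and node.support is not None:
                assert 0.5 < node.support <= 1.0


class TestSplitMaxdiff:
    def test_identical_samples_zero(self):
        s = [parse_newick("((A,B),(C,D));")] * 3
        assert split_maxdiff(s, s) == 0.0

    def test_disjoint_split_sets_one(self):
        a = [parse_newick("((A,B),(C,D));")]
        b = [parse_newick("((A,C),(B,D));")]
        assert split_maxdiff(a, b) == 1.0

    def test_partial_overlap(self):
        ab = parse_newick("((A,B),(C,D),E);")
        star = parse_newick("(A,B,C,D,E);")
        sample_a = [ab] * 4 + [star]  # AB|CDE at 0.8
        sample_b = [ab] * 3 + [star] * 2  # AB|CDE at 0.6
        assert split_maxdiff(sample_a, sample_b) == pytest.approx(0.2)

    def test_symmetry_and_convergence_verdict(self, rng):
        a = [random_tree([f"T{j}" for j in range(6)], rng) for _ in range(5)]
        b = [random_tree([f"T{j}" for j in range(6)], rng) for _ in range(5)]
        assert split_maxdiff(a, b) == pytest.approx(split_maxdiff(b, a))
        assert chains_converged(a, a)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            split_maxdiff([], [parse_newick("(A,B,C);")])
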