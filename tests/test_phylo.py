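import numpy as np
import pytest

from cakl.distance import DistanceMatrix
from cakl.phylo import (
    TreeNode,
    avg_purity,
    label_purity,
    partition_purity,
    upgma,
    write_newick,
    write_purity_report,
)


def dm_from(ids, D):
    return DistanceMatrix(ids=tuple(ids), D=np.asarray(D, dtype=float))


def leaf(name):
    return TreeNode(name=name)


def join(h, *children):
    return TreeNode(height=h, children=list(children))


class TestUpgma:
    def test_three_leaf_hand_computation(self):
        dm = dm_from("abc", [[0, 2, 8], [2, 0, 8], [8, 8, 0]])
        tree = upgma(dm)
        assert write_newick(tree) == "((a:1.0,b:1.0):3.0,c:4.0);"

    def test_two_leaves(self):
        tree = upgma(dm_from("ab", [[0, 3], [3, 0]]))
        assert write_newick(tree) == "(a:1.5,b:1.5);"

    def test_equal_distances_tie_rule_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = write_newick(upgma(dm_from("dcba", D)))
        t2 = write_newick(upgma(dm_from("dcba", D)))
        assert t1 == t2
        # lexicographic rule merges (a, b) first
        assert "(a:0.5,b:0.5)" in t1 or "(b:0.5,a:0.5)" in t1

    def test_ultrametric(self, rng):
        n = 10
        X = rng.normal(size=(n, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        tree = upgma(dm_from([f"s{i}" for i in range(n)], D))

        def depths(node, acc=0.0):
            if node.is_leaf:
                return [acc]
            return [
                d
                for c in node.children
                for d in depths(c, acc + node.height - c.height)
            ]

        ds = depths(tree)
        assert max(ds) - min(ds) < 1e-9

    def test_matches_scipy_average_linkage_heights(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        X = rng.normal(size=(8, 4))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        tree = upgma(dm_from([f"s{i}" for i in range(8)], D))
        ours = sorted(
            round(n.height * 2, 9) for n in tree.postorder() if not n.is_leaf
        )
        scipy_heights = sorted(round(h, 9) for h in average(squareform(D))[:, 2])
        assert ours == scipy_heights

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            upgma(dm_from("ab", [[0, np.nan], [np.nan, 0]]))


class TestNewick:
    def test_round_trip_through_dendropy(self, rng):
        import dendropy

        X = rng.normal(size=(6, 2))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        ids = [f"s{i}" for i in range(6)]
        tree = upgma(dm_from(ids, D))
        s = write_newick(tree)
        parsed = dendropy.Tree.get(data=s, schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == ids
        # bipartitions of our tree survive the round trip
        our_clades = {
            frozenset(n.leaf_names()) for n in tree.postorder() if not n.is_leaf
        }
        their_clades = {
            frozenset(l.taxon.label for l in n.leaf_iter())
            for n in parsed.preorder_node_iter()
            if not n.is_leaf()
        }
        assert our_clades <= their_clades

    def test_names_with_spaces_quoted(self):
        tree = join(1.0, leaf("taxon one"), leaf("b"))
        assert write_newick(tree).startswith("('taxon one':1.0,b:1.0)")


class TestPartitionPurity:
    @pytest.mark.parametrize(
        "sizes,n,expected",
        [([10], 10, 1.0), ([1] * 10, 10, 0.1), ([9, 1], 10, 0.82), ([5, 5], 10, 0.5)],
    )
    def test_extremes_and_dominated(self, sizes, n, expected):
        assert partition_purity(sizes, n) == pytest.approx(expected)

    def test_dominated_strictly_below_one(self):
        for n in range(2, 30):
            assert partition_purity([n - 1, 1], n) < 1.0

    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            partition_purity([3, 3], 5)


class TestLabelPurity:
    def balanced_tree(self):
        # ((a1,a2),(b1,b2)) with label A monophyletic
        return join(
            2.0, join(1.0, leaf("a1"), leaf("a2")), join(1.0, leaf("b1"), leaf("b2"))
        )

    def test_monophyletic_label(self):
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        score, part = label_purity(self.balanced_tree(), labels, "A")
        assert score == 1.0 and part.block_sizes == [2]

    def test_isolated_leaves_give_reciprocal(self):
        # caterpillar alternating labels: every A is a singleton block
        tree = join(3.0, leaf("a1"), join(2.0, leaf("b1"), join(1.0, leaf("a2"), leaf("b2"))))
        labels = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        score, part = label_purity(tree, labels, "A")
        assert score == pytest.approx(0.5) and sorted(part.block_sizes) == [1, 1]

    def test_caterpillar_worked_example(self):
        # leaves A,A,B,A along a caterpillar: blocks {A,A} and {A} -> 5/9
        tree = join(
            3.0,
            join(1.0, leaf("x1"), leaf("x2")),
            join(2.0, leaf("y"), leaf("x3")),
        )
        labels = {"x1": "A", "x2": "A", "y": "B", "x3": "A"}
        score, part = label_purity(tree, labels, "A")
        assert score == pytest.approx(5 / 9)
        assert sorted(part.block_sizes) == [1, 2]

    def test_unlabeled_leaf_named_in_error(self):
        with pytest.raises(ValueError, match="b2"):
            label_purity(self.balanced_tree(), {"a1": "A", "a2": "A", "b1": "B"}, "A")


class TestAvgPurity:
    def test_perfect_and_mixed(self):
        tree = join(
            3.0,
            join(1.0, leaf("a1"), leaf("a2")),
            join(2.0, join(0.5, leaf("b1"), leaf("c1")), join(0.5, leaf("b2"), leaf("c2"))),
        )
        # A monophyletic (1.0); B and C each split into two singletons (0.5 each)
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "c2": "C"}
        result = avg_purity(tree, labels)
        assert result.per_label == {"A": 1.0, "B": 0.5, "C": 0.5}
        assert result.average == pytest.approx(2 / 3)

    def test_single_label_everywhere(self):
        tree = join(1.0, leaf("x"), leaf("y"))
        result = avg_purity(tree, {"x": "L", "y": "L"})
        assert result.average == 1.0

    def test_report_file(self, tmp_path):
        tree = join(1.0, leaf("x"), leaf("y"))
        result = avg_purity(tree, {"x": "L", "y": "L"})
        p = tmp_path / "purity.tsv"
        write_purity_report(result, p)
        text = p.read_text()
        assert "avg_purity" in text and "L\t2\t1\t1.000000" in text
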