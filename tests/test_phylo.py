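"""Protein distances, neighbor joining, bootstrap, split comparison."""

import math

import numpy as np
import pytest

import famevol as fv
from famevol.errors import InputError, SaturationError, UndefinedDistanceError
from famevol.phylo import DistanceMatrix, splits
from famevol.trees import PhyloTree


def path_length_matrix(tree: PhyloTree, labels):
    """Leaf-to-leaf path lengths, computed by brute force from the newick."""
    parent = {}
    for n in tree.preorder():
        for c in n.children:
            parent[id(c)] = n
    leaves = {l.name: l for l in tree.leaves}

    def path_to_root(node):
        out = []
        while id(node) in parent:
            out.append(node)
            node = parent[id(node)]
        return out

    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i >= j:
                continue
            pa, pb = path_to_root(leaves[a]), path_to_root(leaves[b])
            sa = {id(x) for x in pa}
            shared = [x for x in pb if id(x) in sa]
            if shared:
                top = shared[0]
                ia = [id(x) for x in pa].index(id(top))
                ib = [id(x) for x in pb].index(id(top))
                d = sum(x.length for x in pa[:ia]) + sum(x.length for x in pb[:ib])
            else:
                d = sum(x.length for x in pa) + sum(x.length for x in pb)
            D[i, j] = D[j, i] = d
    return D


class TestProteinDistance:
    def test_identical_rows_zero(self):
        rows = [("a", "MKVL"), ("b", "MKVL")]
        for model in ("p", "poisson"):
            D = fv.protein_distance_matrix(rows, model=model)
            assert D.values[0, 1] == 0.0

    def test_half_different_poisson(self):
        rows = [("a", "MKVL"), ("b", "MRVI")]
        D = fv.protein_distance_matrix(rows, model="poisson")
        assert D.values[0, 1] == pytest.approx(-math.log(0.5), abs=1e-4)

    def test_hand_counts_with_gaps(self):
        rows = [("a", "MKV-"), ("b", "MKIX"), ("c", "MRVA"), ("d", "LRVA")]
        D = fv.protein_distance_matrix(rows, model="p")
        # pairwise deletion: a-b over 3 cols 1 diff; a-c over 3 cols 1 diff;
        # a-d over 3 cols 2 diff; b-c over 3 cols 2; b-d 3; c-d over 4 cols 1
        expected = {
            (0, 1): 1 / 3, (0, 2): 1 / 3, (0, 3): 2 / 3,
            (1, 2): 2 / 3, (1, 3): 1.0, (2, 3): 1 / 4,
        }
        for (i, j), p in expected.items():
            assert D.values[i, j] == pytest.approx(p)

    def test_poisson_exceeds_p(self):
        rows = [("a", "MKVLAA"), ("b", "MRVIAA")]
        Dp = fv.protein_distance_matrix(rows, model="p")
        Dc = fv.protein_distance_matrix(rows, model="poisson")
        assert Dc.values[0, 1] > Dp.values[0, 1] > 0

    def test_no_shared_columns(self):
        rows = [("a", "MK--"), ("b", "--VL"), ("c", "MKVL")]
        with pytest.raises(UndefinedDistanceError):
            fv.protein_distance_matrix(rows)

    def test_saturation_names_pair(self):
        rows = [("a", "MK"), ("b", "LR"), ("c", "MK")]
        with pytest.raises(SaturationError, match="a.*b"):
            fv.protein_distance_matrix(rows, model="poisson")


class TestNeighborJoining:
    def test_three_taxa_three_point(self):
        D = DistanceMatrix(("A", "B", "C"),
                           np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], float))
        t = fv.nj_tree(D)
        lengths = {l.name: l.length for l in t.leaves}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(4.0)

    @pytest.mark.parametrize("newick", [
        "((A:1,B:2):1.5,(C:3,D:4):0.5);",
        "(((A:0.4,B:0.7):0.3,C:1.1):0.6,(D:0.9,E:0.2):0.8);",
    ])
    def test_additive_matrix_recovered_exactly(self, newick):
        true = PhyloTree.from_newick(newick)
        labels = sorted(true.leaf_names)
        D = DistanceMatrix(tuple(labels), path_length_matrix(true, labels))
        est = fv.nj_tree(D)
        assert np.allclose(
            path_length_matrix(est, labels), D.values, atol=1e-10
        )
        assert fv.compare_topologies(true, est)["rf_distance"] == 0

    def test_tie_breaks_deterministic(self):
        # fully symmetric distances: every Q value ties
        D = DistanceMatrix(("A", "B", "C", "D"), np.ones((4, 4)) - np.eye(4))
        t1 = fv.nj_tree(D)
        t2 = fv.nj_tree(D)
        assert t1.to_newick() == t2.to_newick()
        # the lowest-index pair (A, B) is joined first
        assert {"A", "B"} in [set(s) for s in splits(t1)] or len(splits(t1)) == 1

    def test_too_few_taxa(self):
        D = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float))
        with pytest.raises(InputError):
            fv.nj_tree(D)

    def test_negative_lengths_clamped(self):
        d = np.array([
            [0.0, 0.1, 0.9, 1.0],
            [0.1, 0.0, 1.0, 0.9],
            [0.9, 1.0, 0.0, 0.1],
            [1.0, 0.9, 0.1, 0.0],
        ])
        t = fv.nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        for n in t.postorder():
            assert n.length >= 0.0

    def test_matches_skbio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(4)
        pts = rng.random((6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = tuple("ABCDEF")
        mine = fv.nj_tree(DistanceMatrix(labels, d))
        ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=list(labels)))
        ref_tree = PhyloTree.from_newick(str(ref))
        assert fv.compare_topologies(mine, ref_tree)["rf_distance"] == 0


class TestCompareTopologies:
    def test_identical_trees(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert fv.compare_topologies(t, t)["rf_distance"] == 0

    def test_conflicting_quartets(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert fv.compare_topologies(t1, t2)["rf_distance"] == 2

    def test_leaf_set_mismatch(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,E:1):1);")
        with pytest.raises(InputError):
            fv.compare_topologies(t1, t2)

    def test_rf_bounded_by_internal_edges(self, rng):
        for _ in range(10):
            pts = rng.random((5, 2))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = tuple("ABCDE")
            t1 = fv.nj_tree(DistanceMatrix(labels, d))
            pts2 = rng.random((5, 2))
            d2 = np.sqrt(((pts2[:, None] - pts2[None]) ** 2).sum(-1))
            t2 = fv.nj_tree(DistanceMatrix(labels, d2))
            res = fv.compare_topologies(t1, t2)
            assert res["rf_distance"] <= 2 * 2  # 5 taxa: 2 internal edges


class TestBootstrap:
    def test_duplicated_strong_blocks_support_100(self):
        # every variable column carries the same xxyy pattern, so each
        # resample supports the single split with certainty
        block = {
            "A": "MKLVAAAA", "B": "MKLVAAAA", "C": "FRSGAAAA", "D": "FRSGAAAA",
        }
        rows = [(k, v * 6) for k, v in block.items()]
        bt = fv.bootstrap_support(rows, B=50, seed=1)
        sup = [int(n.label) for n in bt.postorder()
               if n.label is not None and not n.is_leaf]
        assert sup and all(s == 100 for s in sup)

    def test_single_replicate_binary_support(self):
        rows = [("A", "MKVLIE"), ("B", "MKVLID"), ("C", "MRVAID"), ("D", "LRVAIE")]
        bt = fv.bootstrap_support(rows, B=1, seed=3)
        sup = [int(n.label) for n in bt.postorder()
               if n.label is not None and not n.is_leaf]
        assert all(s in (0, 100) for s in sup)

    def test_invariant_to_taxon_order(self):
        rows = [("A", "MKVLIE"), ("B", "MKVLID"), ("C", "MRVAID"), ("D", "LRVAIE")]
        b1 = fv.bootstrap_support(rows, B=40, seed=5)
        b2 = fv.bootstrap_support(rows[::-1], B=40, seed=5)

        def support_map(t):
            out = {}
            all_leaves = frozenset(t.leaf_names)
            anchor = min(all_leaves)
            for n in t.postorder():
                if n.is_leaf or n is t.root or n.label is None:
                    continue
                side = frozenset(l.name for l in _leaves(n))
                if anchor in side:
                    side = all_leaves - side
                out[side] = n.label
            return out

        def _leaves(node):
            return [x for x in _walk(node) if not x.children]

        def _walk(node):
            yield node
            for c in node.children:
                yield from _walk(c)

        assert support_map(b1) == support_map(b2)
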