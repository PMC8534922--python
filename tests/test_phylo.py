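"""phylo: distances, NJ, balanced-ME search, rooting, Robinson-Foulds."""

import itertools
import math

import numpy as np
import pytest

from paraloglens.evaluation import exhaustive_bme_optimum, random_additive_matrix
from paraloglens.phylo import (
    Correction,
    DistanceMatrix,
    PhyloTree,
    all_topologies,
    bme_tree_length,
    distance_matrix,
    fit_branch_lengths_ols,
    me_tree,
    nj_tree,
    robinson_foulds,
    root_tree,
    root_to_tip_lengths,
    unroot,
)
from paraloglens.records import Alignment


def _additive_dm():
    """Distances exactly additive on ((A,B),(C,D)) with internal edge 0.3."""
    taxa = ["A", "B", "C", "D"]
    d = np.array(
        [
            [0.0, 0.3, 0.9, 1.0],
            [0.3, 0.0, 1.0, 1.1],
            [0.9, 1.0, 0.0, 0.5],
            [1.0, 1.1, 0.5, 0.0],
        ]
    )
    return DistanceMatrix(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        aln = Alignment(["a", "b", "c"], ["ACDE", "ACDE", "ACDF"])
        for corr in (Correction.P, Correction.POISSON):
            dm = distance_matrix(aln, corr)
            assert dm.d[0, 1] == 0.0

    def test_poisson_closed_form(self):
        aln = Alignment(["a", "b", "c"], ["ACDE", "ACDF", "AGDE"])
        dm = distance_matrix(aln, Correction.POISSON)
        assert dm.d[0, 1] == pytest.approx(-math.log(0.75), abs=1e-9)
        dm_p = distance_matrix(aln, Correction.P)
        assert dm_p.d[0, 1] == pytest.approx(0.25)

    def test_pairwise_deletion_hand_counts(self):
        # gaps and X excluded pair-by-pair, not alignment-wide
        aln = Alignment(
            ["a", "b", "c", "d", "e"],
            ["AC-EF", "ACDEF", "GC-EF", "AXDEF", "ACDE-"],
        )
        dm = distance_matrix(aln, Correction.P)
        taxa = aln.ids
        rows = {sid: aln.row(sid) for sid in taxa}

        def hand_p(x, y):
            pairs = [
                (p, q) for p, q in zip(rows[x], rows[y])
                if p not in "-X" and q not in "-X"
            ]
            return sum(1 for p, q in pairs if p != q) / len(pairs)

        for i, j in itertools.combinations(range(5), 2):
            assert dm.d[i, j] == pytest.approx(hand_p(taxa[i], taxa[j]))

    def test_saturation_error_names_pair(self):
        aln = Alignment(["a", "b", "c"], ["AAAA", "CCCC", "AACC"])
        with pytest.raises(ValueError, match="'a' vs 'b'"):
            distance_matrix(aln, Correction.POISSON)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        tree = nj_tree(DistanceMatrix(taxa=["x", "y", "z"], d=d))
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["x"] == pytest.approx((0.4 + 0.6 - 0.8) / 2)
        assert lengths["y"] == pytest.approx((0.4 + 0.8 - 0.6) / 2)
        assert lengths["z"] == pytest.approx((0.6 + 0.8 - 0.4) / 2)

    def test_recovers_additive_split(self):
        tree = nj_tree(_additive_dm())
        assert frozenset({"A", "B"}) in tree.bipartitions()

    def test_matches_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(11)
        dm, true_tree = random_additive_matrix(7, rng)
        ours = nj_tree(dm)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=dm.taxa)
        theirs = PhyloTree.from_newick(str(skbio.tree.nj(sk_dm)))
        assert robinson_foulds(ours, theirs) == 0


# ---------------------------------------------------------------------------
# Balanced minimum evolution
# ---------------------------------------------------------------------------

class TestBmeLength:
    def test_three_leaf_star_hand_value(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(taxa=["a", "b", "c"], d=d)
        tree = nj_tree(dm)
        assert bme_tree_length(tree, dm) == pytest.approx(0.75)

    def test_true_topology_minimal_among_four_leaf_trees(self):
        dm = _additive_dm()
        scored = [
            (bme_tree_length(tree, dm), tree) for tree in all_topologies(dm.taxa)
        ]
        assert len(scored) == 3
        best_tree = min(scored, key=lambda x: x[0])[1]
        assert frozenset({"A", "B"}) in best_tree.bipartitions()

    def test_linearity_in_distances(self):
        dm = _additive_dm()
        tree = nj_tree(dm)
        scaled = DistanceMatrix(taxa=dm.taxa, d=3.0 * dm.d)
        assert bme_tree_length(tree, scaled) == pytest.approx(
            3.0 * bme_tree_length(tree, dm)
        )


class TestMeTree:
    def test_matches_exhaustive_on_additive_matrices(self):
        rng = np.random.default_rng(5)
        for n_taxa in (5, 6):
            for _ in range(5):
                dm, true_tree = random_additive_matrix(n_taxa, rng)
                found = me_tree(dm)
                _, best_len = exhaustive_bme_optimum(dm)
                assert bme_tree_length(found, dm) == pytest.approx(
                    best_len, abs=1e-9
                )
                assert robinson_foulds(found, true_tree) == 0

    def test_never_worse_than_nj(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            d = rng.uniform(0.1, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(taxa=[f"t{i}" for i in range(n)], d=d)
            assert (
                bme_tree_length(me_tree(dm), dm)
                <= bme_tree_length(nj_tree(dm), dm) + 1e-12
            )

    def test_invariant_to_taxa_order(self):
        rng = np.random.default_rng(17)
        dm, _ = random_additive_matrix(6, rng)
        perm = list(rng.permutation(len(dm.taxa)))
        shuffled = DistanceMatrix(
            taxa=[dm.taxa[i] for i in perm], d=dm.d[np.ix_(perm, perm)]
        )
        assert robinson_foulds(me_tree(dm), me_tree(shuffled)) == 0

    def test_ols_branch_lengths_recover_additive_lengths(self):
        rng = np.random.default_rng(23)
        dm, true_tree = random_additive_matrix(6, rng)
        found = me_tree(dm)
        # on an additive matrix, OLS lengths reproduce the leaf-path metric
        names = dm.taxa
        got = _pairwise_path_lengths(found)
        for i, j in itertools.combinations(range(len(names)), 2):
            assert got[(names[i], names[j])] == pytest.approx(
                dm.d[i, j], abs=1e-8
            )


def _pairwise_path_lengths(tree):
    out = {}
    leaves = tree.leaves()
    for a, b in itertools.combinations(leaves, 2):
        anc = {}
        cur, acc = a, 0.0
        while cur is not None:
            anc[id(cur)] = acc
            acc += cur.length
            cur = cur.parent
        cur, acc = b, 0.0
        while id(cur) not in anc:
            acc += cur.length
            cur = cur.parent
        key = tuple(sorted([a.name, b.name]))
        out[(key[0], key[1])] = acc + anc[id(cur)]
    return out


# ---------------------------------------------------------------------------
# Rooting and comparison
# ---------------------------------------------------------------------------

class TestRooting:
    def _four_leaf(self):
        return PhyloTree.from_newick(
            "((A:0.1,B:0.2):0.3,C:0.4,D:0.5);", rooted=False
        )

    def test_single_outgroup(self):
        rooted = root_tree(self._four_leaf(), {"A"})
        assert rooted.rooted
        first = rooted.root.children[0]
        assert {leaf.name for leaf in first.leaves()} == {"A"}
        assert first.length == pytest.approx(0.05)

    def test_non_monophyletic_outgroup(self):
        with pytest.raises(ValueError, match="not monophyletic"):
            root_tree(self._four_leaf(), {"A", "C"})

    def test_root_unroot_roundtrip(self):
        tree = self._four_leaf()
        rooted = root_tree(tree, {"A", "B"})
        back = unroot(rooted)
        assert robinson_foulds(back, tree) == 0

    def test_ultrametric_root_to_tip_equal(self):
        # noise-free clock-like distances -> equal root-to-tip paths
        taxa = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0.0, 0.2, 0.6, 0.6],
                [0.2, 0.0, 0.6, 0.6],
                [0.6, 0.6, 0.0, 0.2],
                [0.6, 0.6, 0.2, 0.0],
            ]
        )
        dm = DistanceMatrix(taxa=taxa, d=d)
        rooted = root_tree(me_tree(dm), {"A", "B"})
        tips = root_to_tip_lengths(rooted)
        spread = max(tips.values()) - min(tips.values())
        assert spread < 1e-9


class TestRobinsonFoulds:
    def test_identical_zero(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);", rooted=False)
        assert robinson_foulds(t, t.copy()) == 0

    def test_single_nni_gives_two(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);", rooted=False)
        t2 = PhyloTree.from_newick("((A:1,C:1):1,B:1,D:1);", rooted=False)
        assert robinson_foulds(t1, t2) == 2

    def test_leaf_set_mismatch(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,C:1,D:1);", rooted=False)
        t2 = PhyloTree.from_newick("((A:1,B:1):1,C:1,E:1);", rooted=False)
        with pytest.raises(ValueError, match="leaf sets"):
            robinson_foulds(t1, t2)

    def test_matches_dendropy(self):
        import dendropy

        rng = np.random.default_rng(31)
        for _ in range(10):
            dm1, t1 = random_additive_matrix(8, rng)
            dm2, t2 = random_additive_matrix(8, rng)
            ours = robinson_foulds(t1, t2)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            theirs = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert ours == theirs


class TestNewick:
    def test_roundtrip(self):
        nwk = "((A:0.100000,B:0.200000):0.300000,C:0.400000,D:0.500000);"
        tree = PhyloTree.from_newick(nwk)
        back = PhyloTree.from_newick(tree.to_newick())
        assert robinson_foulds(tree, back) == 0
        assert sorted(tree.leaf_names()) == sorted(back.leaf_names())
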