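"""Neighbor joining, tree distances, monophyly, clade assignment."""

import io as std_io

import numpy as np
import pytest

from lipoarch import synthetic
from lipoarch.errors import DataError, ParameterError
from lipoarch.nj import (
    DistanceMatrix,
    TreeNode,
    assign_by_clade,
    is_monophyletic,
    neighbor_joining,
    tree_to_distances,
)


def bipartitions(tree):
    """Canonical unrooted splits (frozenset pair), trivial ones excluded."""
    leaves = frozenset(tree.leaf_names())
    splits = set()
    for node in tree.postorder():
        if node is tree:
            continue
        side = frozenset(node.leaf_names())
        if 1 < len(side) < len(leaves) - 1:
            splits.add(frozenset({side, leaves - side}))
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ["a", "b", "c"], np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        )
        tree = neighbor_joining(d)
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_too_few_taxa_rejected(self):
        d = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ParameterError):
            neighbor_joining(d)

    def test_nan_distances_rejected(self):
        with pytest.raises(DataError):
            DistanceMatrix(
                ["a", "b", "c"],
                np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0]]),
            )

    def test_additive_matrix_recovers_topology_and_lengths(self):
        for seed in range(10):
            tree, dist = synthetic.gen_tree_distances(
                n_taxa=7, noise_sd=0.0, seed=seed
            )
            recovered = neighbor_joining(dist)
            assert bipartitions(recovered) == bipartitions(tree)
            d2 = tree_to_distances(recovered, taxa=dist.taxa)
            assert np.abs(d2.values - dist.values).max() < 1e-9

    def test_taxon_order_permutation_invariance(self):
        _, dist = synthetic.gen_tree_distances(n_taxa=8, noise_sd=0.02, seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(dist.taxa))
        permuted = DistanceMatrix(
            [dist.taxa[i] for i in perm], dist.values[np.ix_(perm, perm)]
        )
        t1 = neighbor_joining(dist)
        t2 = neighbor_joining(permuted)
        assert bipartitions(t1) == bipartitions(t2)

    def test_matches_scikit_bio_on_noised_matrix(self):
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkbioDM

        _, dist = synthetic.gen_tree_distances(n_taxa=9, noise_sd=0.05, seed=11)
        mine = neighbor_joining(dist)
        theirs = skbio_nj(SkbioDM(dist.values, ids=dist.taxa))
        their_splits = set()
        leaves = frozenset(dist.taxa)
        for node in theirs.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(leaves) - 1:
                their_splits.add(frozenset({side, leaves - side}))
        assert bipartitions(mine) == their_splits


class TestTreeDistances:
    def test_star_tree_distances_are_2b(self):
        b = 1.7
        star = TreeNode(
            children=[TreeNode(name=t, length=b) for t in ("a", "b", "c", "d")]
        )
        d = tree_to_distances(star)
        off = d.values[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2 * b)

    def test_newick_round_trip_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        tree, dist = synthetic.gen_tree_distances(n_taxa=6, noise_sd=0.0, seed=2)
        parsed = dendropy.Tree.get(
            data=tree.to_newick(), schema="newick"
        )
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        for i, a in enumerate(dist.taxa):
            for j, b in enumerate(dist.taxa):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        dist.values[i, j], abs=1e-9
                    )

    def test_nj_round_trip_on_random_additive_trees(self):
        for seed in range(20):
            n = 5 + seed % 6
            tree, dist = synthetic.gen_tree_distances(n, noise_sd=0.0, seed=seed)
            recovered = neighbor_joining(dist)
            again = tree_to_distances(recovered, taxa=dist.taxa)
            assert np.abs(again.values - dist.values).max() < 1e-9


class TestMonophyly:
    def test_single_leaf_and_full_set_are_monophyletic(self):
        tree, _ = synthetic.gen_tree_distances(6, seed=1)
        leaves = tree.leaf_names()
        assert is_monophyletic(tree, [leaves[0]])
        assert is_monophyletic(tree, leaves)

    def test_unknown_taxon_rejected(self):
        tree, _ = synthetic.gen_tree_distances(5, seed=1)
        with pytest.raises(DataError):
            is_monophyletic(tree, ["nope"])

    def test_matches_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(5)
        for seed in range(8):
            tree, _ = synthetic.gen_tree_distances(8, seed=seed)
            leaves = frozenset(tree.leaf_names())
            all_sides = set()
            for node in tree.postorder():
                if node is tree:
                    continue
                side = frozenset(node.leaf_names())
                all_sides.add(side)
                all_sides.add(leaves - side)
            for _ in range(30):
                k = int(rng.integers(1, len(leaves)))
                subset = frozenset(
                    rng.choice(sorted(leaves), size=k, replace=False)
                )
                expected = subset in all_sides or subset == leaves
                assert is_monophyletic(tree, subset) == expected


class TestCladeAssignment:
    def test_query_sister_to_single_reference(self):
        # ((q:1, ref:1):1, out1:1, out2:1);
        tree = TreeNode(
            children=[
                TreeNode(
                    children=[
                        TreeNode(name="q", length=1),
                        TreeNode(name="ref", length=1),
                    ],
                    length=1,
                ),
                TreeNode(name="out1", length=1),
                TreeNode(name="out2", length=1),
            ]
        )
        assert assign_by_clade(tree, {"ref": "LipM"}) == {
            "q": "LipM",
            "out1": "LipM",
            "out2": "LipM",
        }

    def test_mixed_reference_clade_is_unassigned(self):
        tree = TreeNode(
            children=[
                TreeNode(
                    children=[
                        TreeNode(name="q", length=1),
                        TreeNode(
                            children=[
                                TreeNode(name="r1", length=1),
                                TreeNode(name="r2", length=1),
                            ],
                            length=1,
                        ),
                    ],
                    length=1,
                ),
                TreeNode(name="out1", length=1),
                TreeNode(name="out2", length=1),
            ]
        )
        got = assign_by_clade(tree, {"r1": "LplA", "r2": "LipM"}, queries=["q"])
        assert got == {"q": "unassigned"}

    def test_no_references_rejected(self):
        tree, _ = synthetic.gen_tree_distances(4, seed=0)
        with pytest.raises(ParameterError):
            assign_by_clade(tree, {})

    def test_clade_coherent_simulated_labels_fully_recovered(self):
        """References and queries drawn from the same labelled subtrees must
        all be assigned their subtree's label."""
        for seed in range(5):
            tree, dist = synthetic.gen_tree_distances(10, seed=seed)
            recovered = neighbor_joining(dist)
            # use the two sides of one internal split as "clades"
            splits = sorted(
                bipartitions(recovered),
                key=lambda s: min(len(x) for x in s),
                reverse=True,
            )
            side_a, side_b = sorted(splits[0], key=lambda s: tuple(sorted(s)))
            queries = [sorted(side_a)[0], sorted(side_b)[0]]
            labels = {}
            for taxon in side_a:
                if taxon not in queries:
                    labels[taxon] = "LplA"
            for taxon in side_b:
                if taxon not in queries:
                    labels[taxon] = "LipM"
            got = assign_by_clade(recovered, labels, queries=queries)
            for taxon, label in got.items():
                expected = "LplA" if taxon in side_a else "LipM"
                assert label == expected
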