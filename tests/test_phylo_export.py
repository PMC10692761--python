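"""Distance matrices, neighbour joining and NEXUS/Newick serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from strucphy.phylo_export import (
    DistanceMatrix,
    TreeNode,
    build_distance_matrix,
    neighbor_joining,
    read_nexus_distances,
    sanitize_label,
    write_newick,
    write_nexus,
)


def random_additive_case(n_taxa, seed):
    """A random binary tree and its exact leaf-to-leaf distance matrix."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.uniform(0.001, 0.04))
        b.length = float(rng.uniform(0.001, 0.04))
        nodes.append(TreeNode(children=[a, b]))
    tree = nodes[0]
    taxa = sorted(tree.leaf_names())
    paths = tree.path_distances()
    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            D[i, j] = D[j, i] = paths[(taxa[i], taxa[j])]
    return DistanceMatrix(taxa, D)


def tree_matrix(tree, taxa):
    paths = tree.path_distances()
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = paths[(min(taxa[i], taxa[j]), max(taxa[i], taxa[j]))]
    return out


class TestDistanceMatrix:
    def test_valid_matrix_accepted(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.4, 0.0]]))
        assert D.values[0, 1] == 0.4

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 0.4], [0.5, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.1, 0.4], [0.4, 0.0]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.4], [1.4, 0.0]]))

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], np.zeros((2, 2)))

    def test_build_from_database_stub_maps_sentinel(self):
        class StubDB:
            def pair_qscore(self, a, b):
                return {frozenset({"x", "y"}): 0.75,
                        frozenset({"x", "z"}): -1.0,
                        frozenset({"y", "z"}): 0.25}[frozenset({a, b})]

        D = build_distance_matrix(StubDB(), ["x", "y", "z"])
        assert D.values[0, 1] == pytest.approx(0.25)
        assert D.values[0, 2] == 1.0  # NO_SIMILARITY sentinel -> max distance
        assert D.values[1, 2] == pytest.approx(0.75)


class TestNeighborJoining:
    def test_two_taxa_split_in_half(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 0.6], [0.6, 0.0]]))
        tree = neighbor_joining(D)
        (a, b) = tree.children
        assert {a.name, b.name} == {"a", "b"}
        assert a.length == pytest.approx(0.3)
        assert b.length == pytest.approx(0.3)

    def test_four_taxa_additive_recovered_exactly(self):
        # tree ((A:0.1,B:0.2):0.1,(C:0.15,D:0.25))
        taxa = ["A", "B", "C", "D"]
        D = DistanceMatrix(taxa, np.array([
            [0.00, 0.30, 0.35, 0.45],
            [0.30, 0.00, 0.45, 0.55],
            [0.35, 0.45, 0.00, 0.40],
            [0.45, 0.55, 0.40, 0.00],
        ]))
        tree = neighbor_joining(D)
        assert sorted(tree.leaf_names()) == taxa
        np.testing.assert_allclose(tree_matrix(tree, taxa), D.values, atol=1e-12)

    def test_all_zero_matrix_gives_zero_branches(self):
        D = DistanceMatrix(list("abcde"), np.zeros((5, 5)))
        tree = neighbor_joining(D)
        assert sorted(tree.leaf_names()) == list("abcde")
        assert all(n.length == 0.0 for n in tree.leaves())

    def test_branch_lengths_never_negative(self):
        # near-degenerate matrix that produces negative raw branch estimates
        D = DistanceMatrix(list("abcd"), np.array([
            [0.0, 0.1, 0.1, 0.5],
            [0.1, 0.0, 0.1, 0.5],
            [0.1, 0.1, 0.0, 0.5],
            [0.5, 0.5, 0.5, 0.0],
        ]))
        tree = neighbor_joining(D)

        def walk(node):
            assert node.length >= 0.0
            for c in node.children:
                walk(c)

        walk(tree)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["a"], np.zeros((1, 1))))

    @pytest.mark.parametrize("n,seed", [(4, 1), (6, 2), (8, 3), (12, 4)])
    def test_random_additive_matrices_recovered(self, n, seed):
        D = random_additive_case(n, seed)
        tree = neighbor_joining(D)
        assert sorted(tree.leaf_names()) == D.taxa
        np.testing.assert_allclose(tree_matrix(tree, D.taxa), D.values, atol=1e-10)

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        D = random_additive_case(7, seed=9)
        csv = "," + ",".join(D.taxa) + "\n"
        for t, row in zip(D.taxa, D.values):
            csv += t + "," + ",".join(f"{v:.12f}" for v in row) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        dtable = dtree.phylogenetic_distance_matrix()
        taxon = {t.label: t for t in dtable.taxon_iter()}
        ours = tree_matrix(neighbor_joining(D), D.taxa)
        for i, a in enumerate(D.taxa):
            for j in range(i + 1, len(D.taxa)):
                b = D.taxa[j]
                assert ours[i, j] == pytest.approx(
                    dtable.patristic_distance(taxon[a], taxon[b]), abs=1e-8
                )


class TestSerialisation:
    def test_sanitize_label(self):
        assert sanitize_label("1abc_A") == "1abc_A"
        assert sanitize_label("x.y|z 1") == "x_y_z_1"

    def test_nexus_round_trip(self, tmp_path):
        D = random_additive_case(6, seed=5)
        p = tmp_path / "d.nex"
        write_nexus(D, p)
        text = p.read_text()
        assert text.startswith("#NEXUS")
        assert "NTAX=6" in text
        assert "TRIANGLE=BOTH DIAGONAL" in text
        back = read_nexus_distances(p)
        assert back.taxa == D.taxa
        np.testing.assert_allclose(back.values, D.values, atol=1e-9)

    def test_nexus_label_collision_rejected(self, tmp_path):
        D = DistanceMatrix(["a.b", "a_b"], np.array([[0.0, 0.1], [0.1, 0.0]]))
        with pytest.raises(ValueError):
            write_nexus(D, tmp_path / "bad.nex")

    def test_newick_round_trip_with_dendropy(self, tmp_path):
        dendropy = pytest.importorskip("dendropy")
        D = random_additive_case(6, seed=6)
        tree = neighbor_joining(D)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        text = p.read_text()
        assert text.endswith(";\n")
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        table = parsed.phylogenetic_distance_matrix()
        taxon = {t.label: t for t in table.taxon_iter()}
        ours = tree_matrix(tree, D.taxa)
        for i, a in enumerate(D.taxa):
            for j in range(i + 1, len(D.taxa)):
                b = D.taxa[j]
                assert table.patristic_distance(taxon[a], taxon[b]) == pytest.approx(
                    ours[i, j], abs=1e-5
                )

    @given(st.integers(4, 10), st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_property_nj_additive_and_nexus_stable(self, n, seed):
        D = random_additive_case(n, seed)
        tree = neighbor_joining(D)
        np.testing.assert_allclose(tree_matrix(tree, D.taxa), D.values, atol=1e-9)
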