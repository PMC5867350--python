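"""Tree I/O, pruning, Grafen lengths, ultrametricity, and UPGMA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoevol import datasets
from karyoevol.karyotypes import DivergenceMatrix
from karyoevol.phylo import (
    grafen_lengths,
    is_ultrametric,
    prune_to_taxa,
    read_newick,
    upgma,
    write_newick,
)


class TestNewick:
    def test_parse_basic(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        assert sorted(tree.leaf_names) == ["A", "B", "C"]
        assert len(tree.root.children) == 2

    def test_round_trip_fixture_identical(self):
        path = datasets.data_path("hypopomidae_topology.nwk")
        text = path.read_text().strip()
        assert write_newick(read_newick(path)) == text

    def test_missing_lengths_recorded_absent(self):
        tree = read_newick("((A,B),C);")
        assert all(
            n.parent_edge_length is None for n in tree.root.preorder() if n is not tree.root
        )

    def test_lengths_preserved_to_10_digits(self):
        text = "((A:0.1234567891,B:1):0.9876543211,C:2);"
        assert write_newick(read_newick(text)) == text

    def test_internal_labels_kept(self):
        tree = read_newick("((A:1,B:1)AB:1,C:2)Root;")
        assert tree.find("AB").name == "AB"
        assert tree.root.name == "Root"

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A:1,A:1):1,C:2);")


class TestPrune:
    def test_collapse_unary_with_summed_lengths(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        pruned = prune_to_taxa(tree, ["A", "C"])
        assert sorted(pruned.leaf_names) == ["A", "C"]
        # the A+B cherry node collapses; A keeps its own edge plus the parent edge
        a = pruned.find("A")
        assert a.parent_edge_length == pytest.approx(2.0)

    def test_fixture_prune_to_ingroup(self):
        tree = datasets.load_topology()
        ingroup = [n for n in tree.leaf_names if n.startswith("Brachyhypopomus_")]
        assert len(ingroup) == 11
        pruned = prune_to_taxa(tree, ingroup)
        assert sorted(pruned.leaf_names) == sorted(ingroup)

    def test_single_taxon_rejected(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            prune_to_taxa(tree, ["A"])

    def test_unknown_taxon_listed(self):
        tree = read_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="Z"):
            prune_to_taxa(tree, ["A", "Z"])

    def test_nested_prunes_compose(self):
        tree = grafen_lengths(datasets.load_topology())
        outer = [n for n in tree.leaf_names if n.startswith("Brachyhypopomus_")]
        inner = outer[:5]
        once = prune_to_taxa(tree, inner)
        twice = prune_to_taxa(prune_to_taxa(tree, outer), inner)
        assert write_newick(once) == write_newick(twice)


class TestGrafen:
    def test_balanced_four_leaf(self):
        tree = grafen_lengths(read_newick("((A,B),(C,D));"))
        depths = tree.depths()
        cherry = tree.root.children[0]
        # cherry height (2-1)/(4-1) = 1/3, root at 1
        assert cherry.parent_edge_length == pytest.approx(1 - 1 / 3)
        leaf = cherry.children[0]
        assert leaf.parent_edge_length == pytest.approx(1 / 3)
        for leaf in tree.root.leaves():
            assert depths[id(leaf)] == pytest.approx(1.0)

    def test_two_leaf(self):
        tree = grafen_lengths(read_newick("(A,B);"))
        assert all(leaf.parent_edge_length == pytest.approx(1.0) for leaf in tree.root.leaves())

    def test_caterpillar_cherry_height(self):
        tree = grafen_lengths(read_newick("((A,B),C);"))
        cherry = next(n for n in tree.root.children if not n.is_leaf)
        assert cherry.parent_edge_length == pytest.approx(0.5)

    def test_output_ultrametric_with_unit_root(self, fixture_tree):
        assert is_ultrametric(fixture_tree)
        assert max(fixture_tree.depths().values()) == pytest.approx(1.0)

    def test_idempotent_and_order_invariant(self):
        a = grafen_lengths(read_newick("((A,B),(C,(D,E)));"))
        b = grafen_lengths(grafen_lengths(read_newick("((B,A),((E,D),C));")))
        da, db = a.depths(), b.depths()
        ha = {leaf.name: da[id(leaf)] for leaf in a.root.leaves()}
        hb = {leaf.name: db[id(leaf)] for leaf in b.root.leaves()}
        assert ha == pytest.approx(hb)


class TestUltrametric:
    @pytest.mark.parametrize(
        "text,expected",
        [("((A:1,B:2):1,C:2);", False), ("((A:1,B:1):1,C:2);", True)],
    )
    def test_path_length_check(self, text, expected):
        assert is_ultrametric(read_newick(text)) is expected

    def test_missing_lengths_error(self):
        with pytest.raises(ValueError):
            is_ultrametric(read_newick("((A,B),C);"))


class TestUPGMA:
    def test_two_taxa(self):
        m = DivergenceMatrix(taxa=["A", "B"], values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(m)
        assert all(leaf.parent_edge_length == pytest.approx(1.0) for leaf in tree.root.leaves())

    def test_three_taxa_average_linkage(self):
        m = DivergenceMatrix(
            taxa=["A", "B", "C"],
            values=np.array([[0.0, 2.0, 8.0], [2.0, 0.0, 6.0], [8.0, 6.0, 0.0]]),
        )
        tree = upgma(m)
        depths = tree.depths()
        # A,B join at 1; C joins at (8+6)/2/2 = 3.5
        cherry = next(n for n in tree.root.children if not n.is_leaf)
        assert sorted(leaf.name for leaf in cherry.leaves()) == ["A", "B"]
        assert cherry.children[0].parent_edge_length == pytest.approx(1.0)
        assert max(depths.values()) == pytest.approx(3.5)

    def test_fixture_zero_height_cherries(self, fixture_records_female):
        from karyoevol.karyotypes import divergence_matrix

        tree = upgma(divergence_matrix(fixture_records_female))
        for pair in (
            ("Brachyhypopomus_bennetti", "Brachyhypopomus_walteri"),
            ("Brachyhypopomus_pinnicaudatus", "Brachyhypopomus_gauderio"),
        ):
            mrca = tree.mrca(pair)
            assert sorted(leaf.name for leaf in mrca.leaves()) == sorted(pair)
            depths = tree.depths()
            assert depths[id(mrca.children[0])] - depths[id(mrca)] == pytest.approx(0.0)

    def test_matches_scipy_average_linkage_heights(self):
        # independent oracle: scipy's average linkage on the same matrix
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42)
        for _ in range(5):
            n = 6
            d = np.round(rng.uniform(1, 10, size=(n, n)), 3)
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            m = DivergenceMatrix(taxa=[f"t{i}" for i in range(n)], values=d)
            tree = upgma(m)
            depths = tree.depths()
            z = average(squareform(d))
            assert max(depths.values()) == pytest.approx(z[-1, 2] / 2)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_always_ultrametric(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        d = rng.uniform(0, 5, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        m = DivergenceMatrix(taxa=[f"t{i}" for i in range(n)], values=d)
        assert is_ultrametric(upgma(m), tolerance=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DivergenceMatrix(taxa=["A", "B"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))
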