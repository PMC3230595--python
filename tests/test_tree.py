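"""Tree parsing, branch-length schemes and Brownian covariance."""

import math

import numpy as np
import pytest

from phylodigit import (
    assign_branch_lengths,
    parse_newick,
    phylo_covariance,
    resolve_polytomies,
)
from phylodigit.errors import (
    BranchLengthError,
    ConfigurationError,
    NewickParseError,
    TreeValidationError,
)

from conftest import brute_force_covariance, random_tree


class TestParsing:
    def test_basic_tree(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert len(t.dtree.seed_node.child_nodes()) == 2
        assert t.has_branch_lengths()

    def test_polytomy_without_lengths(self):
        t = parse_newick("(A,B,C);")
        assert t.n_tips == 3
        assert not t.is_binary()
        assert not t.has_branch_lengths()

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1;")

    def test_duplicate_tips_raise(self):
        with pytest.raises(TreeValidationError, match="duplicate"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_round_trip_preserves_topology_and_labels(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            t = random_tree(rng, int(rng.integers(3, 10)))
            t2 = parse_newick(t.to_newick())
            assert t2.tip_labels == t.tip_labels
            C1, _ = brute_force_covariance(t)
            C2, _ = brute_force_covariance(t2)
            np.testing.assert_allclose(C1, C2, atol=1e-9)

    def test_fixture_tree_matches_species_table(self, fixture_tree, morphometrics):
        assert fixture_tree.n_tips == 25
        assert set(fixture_tree.tip_labels) == set(morphometrics["species"])
        assert fixture_tree.is_binary()


class TestResolvePolytomies:
    def test_trifurcation_resolved_with_zero_branch(self):
        t = resolve_polytomies(parse_newick("(A,B,C);"), seed=0)
        assert t.is_binary()
        inserted = [
            n.edge.length
            for n in t.dtree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        ]
        assert inserted == [0.0]

    def test_binary_tree_unchanged(self):
        src = "((A:1,B:1):1,C:2);"
        t = resolve_polytomies(parse_newick(src), seed=3)
        assert t.is_binary()
        C1, _ = brute_force_covariance(parse_newick(src))
        C2, _ = brute_force_covariance(t)
        np.testing.assert_allclose(C1, C2)

    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_root_polytomy_inserts_k_minus_2_zero_branches(self, k):
        newick = "(" + ",".join(f"t{i}" for i in range(k)) + ");"
        t = resolve_polytomies(parse_newick(newick), seed=1)
        zeros = [
            n
            for n in t.dtree.preorder_node_iter()
            if n.parent_node is not None
            and not n.is_leaf()
            and n.edge.length == 0.0
        ]
        assert t.is_binary()
        assert len(zeros) == k - 2

    def test_deterministic_for_fixed_seed(self):
        newick = "(A,B,C,D,E);"
        t1 = resolve_polytomies(parse_newick(newick), seed=5)
        t2 = resolve_polytomies(parse_newick(newick), seed=5)
        assert t1.to_newick() == t2.to_newick()


class TestBranchLengths:
    def test_constant_sets_all_to_one(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,(D,E)));"), "constant")
        lengths = [
            n.edge.length
            for n in t.dtree.preorder_node_iter()
            if n.parent_node is not None
        ]
        assert lengths == [1.0] * len(lengths)

    def test_nee_on_balanced_four_tip_tree(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "nee")
        ln2 = math.log(2)
        for node in t.dtree.preorder_node_iter():
            if node.parent_node is not None:
                assert node.edge.length == pytest.approx(ln2)

    def test_grafen_on_balanced_four_tip_tree(self):
        t = assign_branch_lengths(parse_newick("((A,B),(C,D));"), "grafen")
        tip_lengths = {n.edge.length for n in t.dtree.leaf_node_iter()}
        internal = {
            n.edge.length
            for n in t.dtree.preorder_node_iter()
            if n.parent_node is not None and not n.is_leaf()
        }
        assert sorted(tip_lengths) == pytest.approx([1 / 3])
        assert sorted(internal) == pytest.approx([2 / 3])

    def test_schemes_on_unbalanced_six_tip_tree(self):
        # caterpillar (((((A,B),C),D),E),F): hand-derived heights
        src = "(((((A,B),C),D),E),F);"
        nee = assign_branch_lengths(parse_newick(src), "nee")
        depths = nee.root_to_tip_depths()
        assert all(
            d == pytest.approx(math.log(6)) for d in depths.values()
        )
        # tip F attaches at the root: its branch is the full root height
        f_edge = next(
            n.edge.length for n in nee.dtree.leaf_node_iter()
            if n.taxon.label == "F"
        )
        assert f_edge == pytest.approx(math.log(6))

        grafen = assign_branch_lengths(parse_newick(src), "grafen")
        # heights (n_desc - 1)/5 bottom-up: cherry 1/5, then 2/5, 3/5, 4/5, 1
        ab_tip = next(
            n.edge.length for n in grafen.dtree.leaf_node_iter()
            if n.taxon.label == "A"
        )
        assert ab_tip == pytest.approx(1 / 5)
        pagel = assign_branch_lengths(parse_newick(src), "pagel")
        pd = pagel.root_to_tip_depths()
        assert all(d == pytest.approx(5.0) for d in pd.values())

    @pytest.mark.parametrize("method", ["grafen", "pagel", "nee"])
    def test_ultrametric_on_random_binary_trees(self, method):
        rng = np.random.default_rng(11)
        for _ in range(20):
            t = random_tree(rng, int(rng.integers(4, 15)))
            out = assign_branch_lengths(t, method)
            depths = np.array(list(out.root_to_tip_depths().values()))
            assert np.ptp(depths) < 1e-9
            lengths = [
                n.edge.length
                for n in out.dtree.preorder_node_iter()
                if n.parent_node is not None
            ]
            assert min(lengths) >= 0.0

    def test_unknown_method_raises(self):
        with pytest.raises(ConfigurationError):
            assign_branch_lengths(parse_newick("(A:1,B:1);"), "clock")


class TestCovariance:
    def test_star_tree_identity(self):
        t = parse_newick("(A:1,B:1,C:1,D:1);")
        C = phylo_covariance(t)
        np.testing.assert_array_equal(C.matrix, np.eye(4))

    def test_three_tip_example(self):
        C = phylo_covariance(parse_newick("((A:1,B:1):1,C:2);"))
        idx = {t: i for i, t in enumerate(C.tip_order)}
        m = C.matrix
        assert m[idx["A"], idx["A"]] == 2
        assert m[idx["A"], idx["B"]] == 1
        assert m[idx["A"], idx["C"]] == 0
        assert m[idx["C"], idx["C"]] == 2

    def test_unset_branch_lengths_raise(self):
        with pytest.raises(BranchLengthError):
            phylo_covariance(parse_newick("(A,B,C);"))

    def test_matches_brute_force_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = random_tree(rng, int(rng.integers(3, 13)))
            C = phylo_covariance(t)
            oracle, tips = brute_force_covariance(t)
            assert C.tip_order == tips
            np.testing.assert_allclose(C.matrix, oracle, atol=1e-10)
            # structural invariants
            np.testing.assert_allclose(C.matrix, C.matrix.T)
            eig = np.linalg.eigvalsh(C.matrix)
            assert eig.min() > -1e-9
            off = C.matrix - np.diag(np.diag(C.matrix))
            assert (off.max(axis=1) <= np.diag(C.matrix) + 1e-12).all()
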