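"""Unit tests for the unrooted-tree model and clan/split primitives."""

import itertools

import dendropy
import numpy as np
import pytest

from clanshield import treeio
from clanshield.treeio import (
    MappingError,
    NewickParseError,
    SpeciesMap,
    Split,
    UnrootedTree,
    avg_branch_length,
    classify_triplet,
    is_clan,
    is_single_copy,
    parse_newick,
    prune_species_duplicates,
    splits,
)

from conftest import random_unrooted_tree


def dendropy_clan_blocks(newick):
    """Independent edge-bipartition oracle via dendropy's split machinery."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    tree.encode_bipartitions(collapse_unrooted_basal_bifurcation=True)
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    blocks = set()
    for edge in tree.preorder_edge_iter():
        if edge.bipartition is None:
            continue
        side = frozenset(
            t.label for t in tree.taxon_namespace
            if edge.bipartition.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
        )
        if side and side != all_leaves:
            blocks.add(side)
            blocks.add(all_leaves - side)
    return blocks


class TestParseNewick:
    def test_four_leaf_tree_has_single_nontrivial_split(self):
        tree = parse_newick("(A,B,(C,D));")
        assert tree.leaves == frozenset("ABCD")
        assert splits(tree) == {Split({"C", "D"}, {"A", "B"})}

    def test_round_trip_preserves_split_set(self, rng):
        for n in (4, 6, 9):
            labels = [f"t{i}" for i in range(n)]
            tree = random_unrooted_tree(labels, rng)
            again = parse_newick(tree.to_newick())
            assert again.split_set() == tree.split_set()
            assert again.leaves == tree.leaves

    def test_branch_lengths_preserved_through_round_trip(self, rng):
        tree = random_unrooted_tree([f"t{i}" for i in range(6)], rng, with_lengths=True)
        again = parse_newick(tree.to_newick())
        for a, b in itertools.combinations(sorted(tree.leaves), 2):
            assert again.path_distance(a, b) == pytest.approx(tree.path_distance(a, b))

    @pytest.mark.parametrize(
        "bad",
        ["((A,B),(C,D)", "((A,A),(C,D));", "", "((A,B),(,D));"],
        ids=["unbalanced", "duplicate-leaf", "empty", "empty-label"],
    )
    def test_malformed_input_raises(self, bad):
        with pytest.raises(NewickParseError):
            parse_newick(bad)

    def test_rooted_and_unrooted_writings_compare_equal(self):
        rooted = parse_newick("((A,B),(C,D));")
        unrooted = parse_newick("(A,B,(C,D));")
        assert rooted == unrooted

    def test_polytomies_preserved(self):
        star = parse_newick("(A,B,C,D);")
        assert splits(star) == frozenset()
        assert star.n_edges == 4


class TestSplits:
    def test_five_leaf_tree_hand_enumeration(self):
        tree = parse_newick("((A,B),(C,D),E);")
        assert {s.smaller for s in splits(tree)} == {frozenset("AB"), frozenset("CD")}

    def test_caterpillar_hand_enumeration(self):
        tree = parse_newick("((((A,B),C),D),E);")
        assert splits(tree) == {
            Split({"A", "B"}, {"C", "D", "E"}),
            Split({"A", "B", "C"}, {"D", "E"}),
        }

    def test_resolved_tree_has_n_minus_3_splits(self, rng):
        for n in range(4, 10):
            tree = random_unrooted_tree([f"t{i}" for i in range(n)], rng)
            assert len(splits(tree)) == n - 3

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            splits(parse_newick("(A,B);"))


class TestIsClan:
    @pytest.mark.parametrize(
        "taxa,expected",
        [({"A", "B"}, True), ({"A", "C"}, False), ({"A", "C", "Z"}, False)],
        ids=["cherry", "no-split", "absent-member-ignored"],
    )
    def test_four_leaf_examples(self, taxa, expected, identity_map):
        tree = parse_newick("((A,B),(C,D));")
        assert is_clan(tree, taxa, identity_map("ABCDZ")) is expected

    def test_vacuous_cases_pass(self, identity_map):
        tree = parse_newick("((A,B),(C,D));")
        sm = identity_map("ABCD")
        assert is_clan(tree, {"A"}, sm)  # one member
        assert is_clan(tree, set(), sm)  # no members
        assert is_clan(tree, {"A", "B", "C", "D"}, sm)  # whole leaf set

    def test_multicopy_taxon_requires_all_leaves_together(self):
        sm = SpeciesMap({"x1": "X", "x2": "X", "y1": "Y", "z1": "Z", "w1": "W"})
        together = parse_newick("((x1,x2),(y1,(z1,w1)));")
        assert is_clan(together, {"X", "Y"}, sm)  # {x1,x2,y1} is a block
        apart = parse_newick("((x1,z1),(x2,(y1,w1)));")
        assert not is_clan(apart, {"X", "Y"}, sm)  # x2 stranded from x1,y1
        # a single present taxon is vacuous even with multiple leaves
        assert is_clan(apart, {"X"}, sm)

    def test_unmapped_leaf_raises(self):
        tree = parse_newick("((A,B),(C,D));")
        with pytest.raises(MappingError):
            is_clan(tree, {"A", "B"}, SpeciesMap({"A": "A", "B": "B", "C": "C"}))

    def test_agrees_with_dendropy_bipartition_oracle(self, rng, identity_map):
        """Exhaustive subset check against an independent split encoding."""
        for _ in range(60):
            n = int(rng.integers(4, 9))
            labels = [f"t{i}" for i in range(n)]
            tree = random_unrooted_tree(labels, rng)
            sm = identity_map(labels)
            oracle_blocks = dendropy_clan_blocks(tree.to_newick())
            for r in range(n + 1):
                for subset in itertools.combinations(labels, r):
                    s = frozenset(subset)
                    expected = len(s) <= 1 or s == tree.leaves or s in oracle_blocks
                    assert is_clan(tree, s, sm) is expected


class TestClassifyTriplet:
    GROUPS = {"anu1": "A", "anu2": "A", "cau1": "C", "gym1": "G", "out1": "out"}

    def _map(self):
        return SpeciesMap({l: l for l in self.GROUPS}, {l: g for l, g in self.GROUPS.items()})

    def test_batrachia_analogue(self):
        tree = parse_newick("((anu1,cau1),(gym1,out1));")
        assert classify_triplet(tree, ("A", "C", "G"), "out", self._map()) == frozenset("AC")

    def test_procera_analogue(self):
        tree = parse_newick("((gym1,cau1),(anu1,out1));")
        assert classify_triplet(tree, ("A", "C", "G"), "out", self._map()) == frozenset("CG")

    def test_interleaved_groups_unresolved(self):
        tree = parse_newick("((anu1,gym1),(cau1,(anu2,out1)));")
        assert classify_triplet(tree, ("A", "C", "G"), "out", self._map()) is None

    def test_missing_group_raises(self):
        tree = parse_newick("((anu1,cau1),(anu2,out1));")
        with pytest.raises(ValueError, match="G"):
            classify_triplet(tree, ("A", "C", "G"), "out", self._map())

    def test_invariant_under_rerooting_and_leaf_order(self):
        variants = [
            "((anu1,cau1),(gym1,out1));",
            "(gym1,(out1,(cau1,anu1)));",
            "((cau1,anu1),(out1,gym1));",
            "(out1,(gym1,(anu1,cau1)));",
        ]
        results = {
            classify_triplet(parse_newick(v), ("A", "C", "G"), "out", self._map())
            for v in variants
        }
        assert results == {frozenset("AC")}


class TestPruneSpeciesDuplicates:
    def test_longest_representative_retained(self):
        sm = SpeciesMap({"spX_1": "X", "spX_2": "X", "spY": "Y", "spZ": "Z"})
        tree = parse_newick("((spX_1,spX_2),spY,spZ);")
        lengths = {"spX_1": 300, "spX_2": 120, "spY": 100, "spZ": 100}
        pruned = prune_species_duplicates(tree, sm, lengths)
        assert pruned.leaves == frozenset({"spX_1", "spY", "spZ"})

    def test_no_duplicate_clans_is_identity(self, rng, identity_map):
        labels = [f"t{i}" for i in range(6)]
        tree = random_unrooted_tree(labels, rng)
        pruned = prune_species_duplicates(tree, identity_map(labels), {l: 100 for l in labels})
        assert pruned == tree

    def test_non_clan_copy_untouched(self):
        sm = SpeciesMap(
            {"spX_1": "X", "spX_2": "X", "spX_3": "X", "spY": "Y", "spZ": "Z"}
        )
        tree = parse_newick("((spX_1,spX_2),(spX_3,spY),spZ);")
        lengths = {"spX_1": 300, "spX_2": 120, "spX_3": 50, "spY": 10, "spZ": 10}
        pruned = prune_species_duplicates(tree, sm, lengths)
        assert pruned.leaves == frozenset({"spX_1", "spX_3", "spY", "spZ"})

    def test_tie_breaks_lexicographically(self):
        sm = SpeciesMap({"b_cpy": "X", "a_cpy": "X", "spY": "Y", "spZ": "Z"})
        tree = parse_newick("((a_cpy,b_cpy),spY,spZ);")
        pruned = prune_species_duplicates(tree, sm, {l: 100 for l in sm.leaf_to_taxon})
        assert "a_cpy" in pruned.leaves and "b_cpy" not in pruned.leaves

    def test_never_changes_taxon_set_nor_grows(self, rng):
        labels = ["x1", "x2", "x3", "y1", "y2", "z1", "w1"]
        taxon = {l: l[0].upper() for l in labels}
        sm = SpeciesMap(taxon)
        for _ in range(25):
            tree = random_unrooted_tree(labels, rng)
            lengths = {l: int(rng.integers(50, 500)) for l in labels}
            pruned = prune_species_duplicates(tree, sm, lengths)
            assert {taxon[l] for l in pruned.leaves} == {taxon[l] for l in tree.leaves}
            assert pruned.n_leaves <= tree.n_leaves

    def test_pruned_tree_is_single_copy_when_all_copies_clanned(self):
        sm = SpeciesMap({"x1": "X", "x2": "X", "y1": "Y", "y2": "Y", "z1": "Z"})
        tree = parse_newick("((x1,x2),((y1,y2),z1));")
        pruned = prune_species_duplicates(tree, sm, {l: 100 for l in sm.leaf_to_taxon})
        assert is_single_copy(pruned, sm)


class TestIsSingleCopy:
    def test_examples(self, identity_map):
        assert is_single_copy(parse_newick("(A,B,C);"), identity_map("ABC"))
        sm = SpeciesMap({"A_1": "A", "A_2": "A", "B": "B", "C": "C"})
        assert not is_single_copy(parse_newick("((A_1,A_2),B,C);"), sm)


class TestAvgBranchLength:
    def test_hand_sum(self):
        assert avg_branch_length(parse_newick("((A:1,B:1):2,C:1,D:1);")) == pytest.approx(1.2)

    def test_constant_lengths(self):
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.1,D:0.1);")
        assert avg_branch_length(tree) == pytest.approx(0.1)

    def test_scaling_linearity(self, rng):
        tree = random_unrooted_tree([f"t{i}" for i in range(7)], rng, with_lengths=True)
        scaled = UnrootedTree.from_edges(
            [(u, v, 3.0 * ln) for u, v, ln in tree.edges()],
            dict(tree._leaf_label),
        )
        assert avg_branch_length(scaled) == pytest.approx(3.0 * avg_branch_length(tree))

    def test_missing_length_raises(self):
        with pytest.raises(ValueError, match="lack branch lengths"):
            avg_branch_length(parse_newick("((A:1,B),C:1,D:1);"))


try:
    from hypothesis import given, settings, strategies as st

    @given(seed=st.integers(0, 10 ** 6), n=st.integers(4, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_resolved_tree_properties_hold_for_arbitrary_shapes(seed, n):
        """Any binary unrooted tree: n-3 nontrivial splits, serialization
        round-trips to an equal tree, and every split block is a clan."""
        tree = random_unrooted_tree(
            [f"t{i}" for i in range(n)], np.random.default_rng(seed)
        )
        assert len(tree.split_set()) == n - 3
        assert parse_newick(tree.to_newick()) == tree
        sm = SpeciesMap.identity(tree.leaves)
        for split in tree.split_set():
            for block in split.blocks:
                assert is_clan(tree, block, sm)
except ImportError:  # pragma: no cover - hypothesis is an optional test extra
    pass


class TestSpeciesMap:
    def test_prefix_fallback(self):
        sm = SpeciesMap({"Homo_sapiens": "Homo_sapiens"})
        assert sm.taxon_of("Homo_sapiens|contig77") == "Homo_sapiens"
        with pytest.raises(MappingError):
            sm.taxon_of("Pan_troglodytes")

    def test_tsv_round_trip(self, tmp_path):
        sp = tmp_path / "species.tsv"
        gp = tmp_path / "groups.tsv"
        sp.write_text("h1\thuman\nm1\tmouse\n")
        gp.write_text("human\tmammals\nmouse\tmammals\n")
        sm = SpeciesMap.from_tsv(sp, gp)
        assert sm.taxon_of("h1") == "human"
        assert sm.group_of("mouse") == "mammals"
        assert sm.taxa_in_group("mammals") == frozenset({"human", "mouse"})
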