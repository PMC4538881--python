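"""Core data model: alignments, masks, trees, splits, pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from filterbench.core import (Alignment, ColumnMask, EmptyAlignmentError,
                              FormatError, Phylotree, apply_mask,
                              column_gap_fraction, fraction_wrong_splits,
                              prune_to_taxa, read_alignment, read_mask,
                              splits_of, write_mask)

from oracles import (adjacency_to_newick, enumerate_unrooted,
                     splits_of_adjacency)


# ---------------------------------------------------------------------------
# Alignment I/O and masking


class TestReadAlignment:
    def test_parses_equal_length_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nAC-\n>b\nACA\n")
        aln = read_alignment(p)
        assert aln.ids == ["a", "b"]
        assert aln.n_cols == 3
        assert list(aln.col_provenance) == [0, 1, 2]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_alignment(p)

    def test_ragged_rows_rejected(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nACA\n>b\nACAA\n")
        with pytest.raises(FormatError):
            read_alignment(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nAC\n>a\nAC\n")
        with pytest.raises(FormatError):
            read_alignment(p)

    def test_gap_dialects_and_case_normalised(self):
        aln = Alignment(["a", "b"], ["ac?g", "A.-G"])
        assert aln.rows == ["AC-G", "A--G"]


class TestApplyMask:
    def test_all_true_is_identity(self):
        aln = Alignment(["a", "b"], ["ACDE", "AC-E"])
        out = apply_mask(aln, ColumnMask(np.ones(4, bool)))
        assert out.rows == aln.rows
        assert list(out.col_provenance) == [0, 1, 2, 3]

    def test_keeps_selected_columns_with_provenance(self):
        aln = Alignment(["a", "b"], ["ACDE", "AC-E"])
        out = apply_mask(aln, ColumnMask(np.array([True, False, True, False])))
        assert out.rows == ["AD", "A-"]
        assert list(out.col_provenance) == [0, 2]

    def test_all_false_flags_family_exclusion(self):
        aln = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(EmptyAlignmentError):
            apply_mask(aln, ColumnMask(np.zeros(2, bool)))

    def test_wrong_length_rejected(self):
        aln = Alignment(["a", "b"], ["AC", "AC"])
        with pytest.raises(FormatError):
            apply_mask(aln, ColumnMask(np.ones(3, bool)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.booleans(), min_size=20, max_size=20),
           st.lists(st.booleans(), min_size=20, max_size=20))
    def test_sequential_masks_compose(self, keep1, keep2):
        """m1 then m2 must equal direct indexing with the composed mask."""
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACDEFG-"), size=20)) for _ in range(4)]
        aln = Alignment([f"s{i}" for i in range(4)], rows)
        keep1 = np.array(keep1)
        if not keep1.any():
            keep1[0] = True
        step1 = apply_mask(aln, ColumnMask(keep1))
        keep2 = np.array(keep2)[: step1.n_cols]
        if not keep2.any():
            keep2[0] = True
        step2 = apply_mask(step1, ColumnMask(keep2))
        composed_cols = np.flatnonzero(keep1)[np.flatnonzero(keep2)]
        expected = ["".join(r[j] for j in composed_cols) for r in aln.rows]
        assert step2.rows == expected
        assert list(step2.col_provenance) == list(composed_cols)


def test_column_gap_fraction():
    aln = Alignment(list("abcd"), ["A-CA", "AAC-", "A-C-", "CAC-"])
    gf = column_gap_fraction(aln)
    assert gf.tolist() == [0.0, 0.5, 0.0, 0.75]


def test_mask_file_round_trip(tmp_path):
    aln = Alignment(["a", "b"], ["ACDEF", "ACD-F"])
    mask = ColumnMask(np.array([True, False, True, False, True]))
    write_mask(mask, aln, tmp_path / "mask.txt")
    assert (tmp_path / "mask.txt").read_text().split() == ["1", "3", "5"]
    back = read_mask(tmp_path / "mask.txt", aln)
    assert back.keep.tolist() == mask.keep.tolist()


# ---------------------------------------------------------------------------
# Trees


class TestTreeIO:
    def test_parse_basic(self):
        t = Phylotree.parse("((a:1,b:1):1,c:2);")
        assert sorted(t.leaf_names()) == ["a", "b", "c"]
        assert t.rooted

    def test_round_trip_preserves_everything(self):
        s = "((a:1.5,b:0.25)0.95:1.0,(c:2.0,d:1.0)0.5:0.125);"
        t = Phylotree.parse(s)
        again = Phylotree.parse(t.to_newick())
        assert splits_of(again).supports == splits_of(t).supports
        assert again.max_root_to_leaf() == t.max_root_to_leaf()

    def test_internal_label_parsed_as_support(self):
        t = Phylotree.parse("((a,b)0.95,(c,d));")
        assert splits_of(t).supports[frozenset({"c", "d"})] == 0.95

    def test_unparseable_rejected(self):
        with pytest.raises(FormatError):
            Phylotree.parse("((a,b),(c,d)")


class TestSplits:
    def test_binary_six_leaf_tree_has_three_splits(self):
        t = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        assert len(splits_of(t)) == 3

    def test_star_tree_has_no_splits(self):
        t = Phylotree.parse("(a,b,c,d,e);")
        assert len(splits_of(t)) == 0

    def test_quartet_single_split(self):
        t = Phylotree.parse("((a,b),(c,d));")
        assert splits_of(t).splits == {frozenset({"c", "d"})}

    def test_fewer_than_four_leaves_empty(self):
        assert len(splits_of(Phylotree.parse("((a,b),c);"))) == 0


class TestFractionWrongSplits:
    def test_identical_trees_score_zero(self):
        t = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        assert fraction_wrong_splits(t, t) == 0.0

    def test_one_nni_on_six_taxa_scores_one_third(self):
        # oracle: split enumeration of both topologies shows exactly one
        # split of the inferred tree absent from the reference
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        nni = Phylotree.parse("(((a,b),d),(c,(e,f)));")
        # canonical encoding: the side not containing leaf "a"
        ref_splits = {frozenset({"c", "d", "e", "f"}),
                      frozenset({"d", "e", "f"}), frozenset({"e", "f"})}
        nni_splits = {frozenset({"c", "d", "e", "f"}),
                      frozenset({"c", "e", "f"}), frozenset({"e", "f"})}
        assert splits_of(ref).splits == ref_splits
        assert splits_of(nni).splits == nni_splits
        assert fraction_wrong_splits(nni, ref) == pytest.approx(1 / 3)

    def test_unresolved_inferred_tree_has_no_wrong_splits(self):
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        star = Phylotree.parse("(a,b,c,d,e,f);")
        assert fraction_wrong_splits(star, ref) == 0.0

    def test_mismatched_leaf_sets_rejected(self):
        a = Phylotree.parse("((a,b),(c,d));")
        b = Phylotree.parse("((a,b),(c,e));")
        with pytest.raises(ValueError):
            fraction_wrong_splits(a, b)

    def test_matches_enumeration_oracle_on_all_six_leaf_topologies(self):
        """Equality with brute-force split enumeration over all 105
        topologies; symmetry; zero iff identical."""
        leaves = list("abcdef")
        adjs = enumerate_unrooted(leaves)
        assert len(adjs) == 105
        oracle_splits = [splits_of_adjacency(a, leaves) for a in adjs]
        trees = [Phylotree.parse(adjacency_to_newick(a, leaves)) for a in adjs]
        for t, s in zip(trees, oracle_splits):
            assert splits_of(t).splits == s
        rng = np.random.default_rng(1)
        idx = rng.integers(0, 105, size=(60, 2))
        for i, j in idx:
            expected = len(oracle_splits[i] - oracle_splits[j]) / 3
            got = fraction_wrong_splits(trees[i], trees[j])
            assert got == pytest.approx(expected)
            assert fraction_wrong_splits(trees[j], trees[i]) == pytest.approx(
                len(oracle_splits[j] - oracle_splits[i]) / 3)
            assert (got == 0.0) == (oracle_splits[i] == oracle_splits[j])


class TestPruneToTaxa:
    def test_full_leaf_set_is_identity(self):
        t = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        p = prune_to_taxa(t, set("abcdef"))
        assert splits_of(p).splits == splits_of(t).splits

    def test_merged_branch_takes_max_support_and_summed_length(self):
        t = Phylotree.parse("((a:1,b:1)0.9:1,(c:1,(d:1,e:1)0.6:0.2)0.95:1);")
        p = prune_to_taxa(t, {"a", "b", "c", "d"})
        # path (c,(d,e)) -> (c,d): d's branch merges the 0.6 edge
        sup = splits_of(p).supports
        assert sup[frozenset({"c", "d"})] == 0.95
        dnode = [nd for nd in p.dendropy_tree.leaf_node_iter()
                 if nd.taxon.label == "d"][0]
        assert dnode.edge.length == pytest.approx(1.2)

    def test_nested_pruning_composes(self):
        t = Phylotree.parse(
            "(((a:1,b:1)0.8:1,(c:1,d:1)0.7:1)0.6:1,((e:1,f:1)0.5:1,(g:1,h:1)0.4:1)0.3:1);")
        big = set("abcdefg")
        small = set("abcef")
        once = prune_to_taxa(t, small)
        twice = prune_to_taxa(prune_to_taxa(t, big), small)
        assert splits_of(once).splits == splits_of(twice).splits
        # merged support can only grow under further merging
        for s, sup in splits_of(twice).supports.items():
            assert sup >= splits_of(t).supports.get(s, 0.0)

    def test_non_subset_rejected(self):
        t = Phylotree.parse("((a,b),(c,d));")
        with pytest.raises(ValueError):
            prune_to_taxa(t, {"a", "b", "c", "x"})
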