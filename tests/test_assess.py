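"""Assessment statistics: discordance, reconciliation, alignment accuracy."""

import numpy as np
import pytest

from filterbench.core import Alignment, ColumnMask, Phylotree, apply_mask
from filterbench.assess import (SpeciesMap, column_precision_recall,
                                enriched_discordance, losses_per_branch,
                                min_duplications, sop_precision, sop_recall,
                                sop_scores, support_decomposition)
from filterbench.filters import make_filter
from filterbench.inference import nj_tree, pairwise_distances
from filterbench.simulate import make_enriched_problem

from oracles import homology_pairs, surviving_pairs


# ---------------------------------------------------------------------------
# Support decomposition


class TestSupportDecomposition:
    def test_perfect_fully_supported_tree(self):
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        perfect = Phylotree.parse("(((a:1,b:1)1.0:1,c:1)1.0:1,(d:1,(e:1,f:1)1.0:1)1.0:1);")
        for th in (0.75, 0.9, 0.95, 0.99):
            assert support_decomposition(perfect, ref, th) == (3, 0, 0)

    def test_all_below_threshold_is_pure_false_negatives(self):
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        weak = Phylotree.parse("(((a:1,b:1)0.2:1,c:1)0.2:1,(d:1,(e:1,f:1)0.2:1)0.2:1);")
        assert support_decomposition(weak, ref, 0.75) == (0, 0, 3)

    def test_single_wrong_split_at_high_support(self):
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        nni = Phylotree.parse("(((a:1,b:1)1.0:1,d:1)0.99:1,(c:1,(e:1,f:1)1.0:1)1.0:1);")
        assert support_decomposition(nni, ref, 0.95) == (2, 1, 1)

    def test_missing_supports_rejected(self):
        ref = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        bare = Phylotree.parse("(((a,b),c),(d,(e,f)));")
        with pytest.raises(ValueError):
            support_decomposition(bare, ref, 0.9)

    def test_count_identity_and_threshold_monotonicity(self):
        """TP+FN equals the n-3 reference splits at every threshold; TP
        never grows and FN never shrinks as the threshold rises."""
        rng = np.random.default_rng(0)
        ref = Phylotree.parse("(((a,b),c),((d,e),(f,(g,h))));")
        n = 8
        for _ in range(20):
            tree = Phylotree.parse(
                "(((a:1,b:1)%f:1,c:1)%f:1,((d:1,e:1)%f:1,(f:1,(g:1,h:1)%f:1)%f:1)0.5:1);"
                % tuple(rng.random(5)))
            prev_tp, prev_fn = None, None
            for th in (0.75, 0.9, 0.95, 0.99):
                tp, fp, fn = support_decomposition(tree, ref, th)
                assert tp + fn == n - 3
                if prev_tp is not None:
                    assert tp <= prev_tp and fn >= prev_fn
                prev_tp, prev_fn = tp, fn


# ---------------------------------------------------------------------------
# Reconciliation criteria


class TestMinDuplications:
    SP = Phylotree.parse("((s1,s2),s3);")

    def test_congruent_single_copy_family_needs_none(self):
        g = Phylotree.parse("((s1_a,s2_a),s3_a);")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2", "s3_a": "s3"}, self.SP)
        assert min_duplications(g, smap) == 0

    def test_two_parallel_copies_need_one_duplication(self):
        sp = Phylotree.parse("(s1,s2);")
        g = Phylotree.parse("((s1_a,s2_a),(s1_b,s2_b));")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2",
                           "s1_b": "s1", "s2_b": "s2"}, sp)
        assert min_duplications(g, smap) == 1

    def test_three_parallel_copies_need_two_duplications(self):
        sp = Phylotree.parse("(s1,s2);")
        g = Phylotree.parse("(((s1_a,s2_a),(s1_b,s2_b)),(s1_c,s2_c));")
        smap = SpeciesMap({f"s{i}_{c}": f"s{i}"
                           for i in (1, 2) for c in "abc"}, sp)
        assert min_duplications(g, smap) == 2

    def test_single_rooting_mode_never_below_minimum(self):
        sp = Phylotree.parse("((s1,s2),s3);")
        # rooted so that the given rooting is suboptimal
        g = Phylotree.parse("(s1_a,(s2_a,(s1_b,(s2_b,s3_a))));")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2", "s1_b": "s1",
                           "s2_b": "s2", "s3_a": "s3"}, sp)
        assert (min_duplications(g, smap, single_rooting=True)
                >= min_duplications(g, smap))

    def test_unmapped_leaf_rejected(self):
        g = Phylotree.parse("((s1_a,s2_a),s3_a);")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2"}, self.SP)
        with pytest.raises(ValueError, match="unmapped"):
            min_duplications(g, smap)

    def test_multifurcation_rejected(self):
        g = Phylotree.parse("((s1_a,s2_a,s3_a),(s1_b,s2_b));")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2", "s3_a": "s3",
                           "s1_b": "s1", "s2_b": "s2"}, self.SP)
        with pytest.raises(ValueError, match="multifurcation"):
            min_duplications(g, smap)


class TestLossesPerBranch:
    def test_congruent_family_has_no_losses(self):
        sp = Phylotree.parse("((s1,s2),s3);")
        g = Phylotree.parse("((s1_a,s2_a),s3_a);")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2", "s3_a": "s3"}, sp)
        assert losses_per_branch(g, smap) == 0.0

    def test_skipped_species_implies_one_loss(self):
        # gene tree (s1_a, s3_a): the s1 lineage skips the (s1,s2) split,
        # implying the loss of s2 on that edge; 2 gene-tree branches
        sp = Phylotree.parse("((s1,s2),s3);")
        g = Phylotree.parse("(s1_a,s3_a);")
        smap = SpeciesMap({"s1_a": "s1", "s3_a": "s3"}, sp)
        assert losses_per_branch(g, smap) == pytest.approx(0.5)

    def test_branch_lengths_are_irrelevant(self):
        sp = Phylotree.parse("((s1,s2),s3);")
        smap = SpeciesMap({"s1_a": "s1", "s3_a": "s3"}, sp)
        a = Phylotree.parse("(s1_a:1,s3_a:1);")
        b = Phylotree.parse("(s1_a:9,s3_a:0.1);")
        assert losses_per_branch(a, smap) == losses_per_branch(b, smap)

    def test_duplication_side_without_copy_counts_loss(self):
        sp = Phylotree.parse("(s1,s2);")
        # duplication at the root, one copy lost in s2 on one side
        g = Phylotree.parse("((s1_a,s2_a),s1_b);")
        smap = SpeciesMap({"s1_a": "s1", "s2_a": "s2", "s1_b": "s1"}, sp)
        assert losses_per_branch(g, smap) == pytest.approx(1 / 4)


# ---------------------------------------------------------------------------
# Alignment accuracy


class TestSumOfPairs:
    def test_truth_against_itself_is_perfect(self, small_family):
        aln = small_family.true_alignment
        assert sop_precision(aln, aln) == 1.0
        assert sop_recall(aln, aln) == 1.0

    def test_column_subsets_keep_precision_one(self, small_family):
        """Any column subset of the truth asserts only true pairs; its
        recall equals the surviving-pair fraction (enumeration oracle)."""
        aln = small_family.true_alignment
        rng = np.random.default_rng(3)
        all_pairs = homology_pairs(aln.rows)
        for _ in range(5):
            keep = rng.random(aln.n_cols) > 0.4
            keep[rng.integers(0, aln.n_cols)] = True
            sub = apply_mask(aln, ColumnMask(keep))
            assert sop_precision(sub, aln) == 1.0
            survived = surviving_pairs(aln.rows, np.flatnonzero(keep))
            fd, fm, empty_t, _ = sop_scores(sub, aln)
            expected = []
            for i in range(aln.n_seqs):
                for j in range(i + 1, aln.n_seqs):
                    tot = sum(1 for p in all_pairs if p[:2] == (i, j))
                    kept_n = sum(1 for p in survived if p[:2] == (i, j))
                    expected.append(kept_n / tot if tot else 1.0)
            assert np.allclose(fm, expected)

    def test_empty_assertion_pairs_flagged_and_counted_one(self):
        """A fully staggered alignment asserts no residue pairs: recall is
        zero, precision takes the documented fD = 1 convention, and the
        pair is flagged so averages can exclude it."""
        true = Alignment(["a", "b"], ["AC", "AC"])
        staggered = Alignment(["a", "b"], ["AC--", "--AC"])
        fd, fm, empty_t, _ = sop_scores(staggered, true)
        assert empty_t.tolist() == [True]
        assert fd.tolist() == [1.0]
        assert fm.tolist() == [0.0]
        assert sop_recall(staggered, true) == 0.0

    def test_different_sequences_rejected(self):
        a = Alignment(["a", "b"], ["AC", "AC"])
        b = Alignment(["a", "b"], ["AG", "AC"])
        with pytest.raises(ValueError):
            sop_precision(b, a)


class TestColumnMeasure:
    def test_truth_is_perfect(self, small_family):
        aln = small_family.true_alignment
        assert column_precision_recall(aln, aln) == (1.0, 1.0)

    def test_removed_columns_hit_recall_only(self):
        true = Alignment(["a", "b", "c"], ["ACD", "ACD", "ACD"])
        sub = apply_mask(true, ColumnMask(np.array([True, True, False])))
        assert column_precision_recall(sub, true) == (1.0, pytest.approx(2 / 3))

    def test_single_row_shift_voids_the_column(self):
        # true keeps the two C residues apart; the test aligns them, so
        # that column matches no true column (all-or-nothing rule)
        true = Alignment(["a", "b"], ["AC-", "A-C"])
        test = Alignment(["a", "b"], ["AC", "AC"])
        p, r = column_precision_recall(test, true)
        assert p == 0.5 and r == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# Enriched discordance pipeline


class TestEnrichedDiscordance:
    def _builder(self, aln):
        return nj_tree(pairwise_distances(aln))

    def test_perfect_pipeline_in_clean_regime(self, clean_family):
        core, ref = make_enriched_problem(clean_family, n_core=5, seed=0)
        rec = enriched_discordance(
            clean_family, core, ref, make_filter("unfiltered"),
            self._builder)
        assert rec.fraction_wrong_splits == 0.0
        assert rec.fraction_removed == 0.0
        assert rec.precision == 1.0 and rec.recall == 1.0

    def test_empty_filter_marks_record_excluded(self, clean_family):
        core, ref = make_enriched_problem(clean_family, n_core=5, seed=0)
        rec = enriched_discordance(
            clean_family, core, ref, make_filter("random", {"fraction": 1.0}),
            self._builder)
        assert rec.excluded

    def test_full_core_reduces_to_plain_discordance(self, clean_family):
        core = set(clean_family.true_tree.leaf_names())
        rec = enriched_discordance(
            clean_family, core, clean_family.true_tree,
            make_filter("unfiltered"), self._builder)
        assert rec.fraction_wrong_splits == 0.0
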