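"""Assessment statistics for filtered alignments.

Implements the benchmark's test batteries: the (enriched) species-tree
discordance test, the support-threshold true/false-positive decomposition,
parsimony reconciliation criteria (minimum duplications over rootings,
implied losses per branch), and alignment accuracy against simulated truth
(sum-of-pairs and true-column precision/recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (Alignment, ColumnMask, EmptyAlignmentError, Phylotree,
                   apply_mask, fraction_wrong_splits, prune_to_taxa, splits_of)

__all__ = [
    "AssessmentRecord", "SpeciesMap", "DEFAULT_SUPPORT_THRESHOLDS",
    "enriched_discordance", "support_decomposition", "min_duplications",
    "losses_per_branch", "sop_precision", "sop_recall", "sop_scores",
    "column_precision_recall",
]

DEFAULT_SUPPORT_THRESHOLDS = (0.75, 0.9, 0.95, 0.99)


# ---------------------------------------------------------------------------
# Records


@dataclass
class AssessmentRecord:
    """One (family x filter setting) outcome."""

    family_id: str
    filter_name: str
    fraction_removed: float = np.nan
    fraction_wrong_splits: float = np.nan
    support_counts: dict = field(default_factory=dict)  # threshold -> (TP, FP, FN)
    duplications: Optional[int] = None
    losses_per_branch: Optional[float] = None
    precision: Optional[float] = None
    recall: Optional[float] = None
    excluded: bool = False
    error: Optional[str] = None


# ---------------------------------------------------------------------------
# Species-tree discordance (enriched variant)


def enriched_discordance(family, core_taxa: Iterable[str],
                         reference: Phylotree,
                         filter_fn: Callable[[Alignment], ColumnMask],
                         tree_builder: Callable[[Alignment], Phylotree],
                         aligner: Optional[Callable[[Mapping[str, str]], Alignment]] = None,
                         support_thresholds: Sequence[float] = (),
                         filter_name: Optional[str] = None) -> AssessmentRecord:
    """Run align -> filter -> infer -> prune -> compare for one family.

    ``aligner`` maps unaligned sequences to an alignment; ``None`` injects
    the family's true alignment (the perfect-aligner limit).  The inferred
    tree is pruned to the core taxa (support-preserving merge) and scored
    against the reference topology.  If filtering removes every column the
    record is marked excluded so the campaign can drop the family for *all*
    methods.  When the family carries a true alignment, sum-of-pairs
    precision/recall of the filtered alignment are recorded too.
    """
    core = set(core_taxa)
    name = filter_name or getattr(filter_fn, "__name__", "filter")
    rec = AssessmentRecord(family_id=str(family.config.seed),
                           filter_name=name)
    aln = family.true_alignment if aligner is None else aligner(family.sequences)
    mask = filter_fn(aln)
    rec.filter_name = filter_name or mask.source
    rec.fraction_removed = mask.fraction_removed
    try:
        filtered = apply_mask(aln, mask)
    except EmptyAlignmentError:
        rec.excluded = True
        rec.error = "filter removed all columns"
        return rec
    tree = tree_builder(filtered)
    pruned = prune_to_taxa(tree, core)
    rec.fraction_wrong_splits = fraction_wrong_splits(pruned, reference)
    for th in support_thresholds:
        rec.support_counts[th] = support_decomposition(pruned, reference, th)
    if family.true_alignment is not None:
        rec.precision = sop_precision(filtered, family.true_alignment)
        rec.recall = sop_recall(filtered, family.true_alignment)
    return rec


def support_decomposition(pruned: Phylotree, reference: Phylotree,
                          threshold: float) -> tuple[int, int, int]:
    """(TP, FP, FN) of the pruned tree's splits at a support threshold.

    Splits with support >= threshold count as resolved: true positives if
    present in the reference, false positives otherwise; reference splits
    not among the resolved splits are false negatives.  The false-positive
    rate FP/(TP+FP) is the fraction of resolved branches that are
    incorrect; FN/(TP+FN) the fraction of reference branches missed.
    """
    ref_splits = splits_of(reference).splits
    got = splits_of(pruned)
    if any(s is None for s in got.supports.values()):
        raise ValueError("pruned tree lacks branch supports")
    resolved = {s for s, sup in got.supports.items() if sup >= threshold}
    tp = len(resolved & ref_splits)
    fp = len(resolved - ref_splits)
    fn = len(ref_splits - resolved)
    return tp, fp, fn


# ---------------------------------------------------------------------------
# Reconciliation criteria


@dataclass
class SpeciesMap:
    """Gene-tree leaf -> species mapping plus the rooted species tree."""

    mapping: dict
    species_tree: Phylotree

    def __post_init__(self) -> None:
        sp_leaves = set(self.species_tree.leaf_names())
        missing = {s for s in self.mapping.values() if s not in sp_leaves}
        if missing:
            raise ValueError(f"species not in species tree: {sorted(missing)}")


class _SpeciesIndex:
    """Bitmask-based LCA lookup over a rooted binary species tree."""

    def __init__(self, species_tree: Phylotree) -> None:
        self.leaf_bit: dict = {}
        self.nodes: list = []        # postorder (mask, depth)
        depth = {}
        for nd in species_tree.dendropy_tree.preorder_node_iter():
            depth[id(nd)] = 0 if nd.parent_node is None else depth[id(nd.parent_node)] + 1
        masks = {}
        for nd in species_tree.dendropy_tree.postorder_node_iter():
            if nd.is_leaf():
                bit = 1 << len(self.leaf_bit)
                self.leaf_bit[nd.taxon.label] = bit
                masks[id(nd)] = bit
            else:
                kids = nd.child_nodes()
                if len(kids) != 2:
                    raise ValueError("species tree must be rooted and binary")
                masks[id(nd)] = masks[id(kids[0])] | masks[id(kids[1])]
            self.nodes.append((masks[id(nd)], depth[id(nd)]))

    def lca(self, mask: int) -> tuple[int, int]:
        """(mask, depth) of the LCA of the species in ``mask``; postorder
        guarantees the first superset node encountered is the LCA."""
        for node_mask, node_depth in self.nodes:
            if mask & node_mask == mask:
                return node_mask, node_depth
        raise ValueError("mask not covered by species tree")


def _gene_adjacency(gene_tree: Phylotree):
    """Unrooted adjacency of a (rooted or unrooted) binary gene tree."""
    adj: dict = {}
    names: dict = {}
    ids: dict = {}

    def nid(nd):
        if id(nd) not in ids:
            ids[id(nd)] = len(ids)
            adj[ids[id(nd)]] = []
        return ids[id(nd)]

    for nd in gene_tree.dendropy_tree.preorder_node_iter():
        u = nid(nd)
        kids = nd.child_nodes()
        if nd.is_leaf():
            names[u] = nd.taxon.label
        elif len(kids) != 2 and nd.parent_node is not None:
            raise ValueError("gene tree has multifurcations; resolve first")
        elif nd.parent_node is None and len(kids) not in (2, 3):
            raise ValueError("gene tree has multifurcations; resolve first")
        if nd.parent_node is not None:
            v = nid(nd.parent_node)
            adj[u].append(v)
            adj[v].append(u)
    for u in list(adj):
        if len(adj[u]) == 2 and u not in names:  # degree-2 root
            a, b = adj[u]
            adj[a] = [x for x in adj[a] if x != u] + [b]
            adj[b] = [x for x in adj[b] if x != u] + [a]
            del adj[u]
    return adj, names


def _count_dups(adj, names, leaf_mask, sp: _SpeciesIndex, root_edge):
    """LCA-reconciliation duplication count for the rooting on root_edge."""
    u, v = root_edge

    def down(x, frm):
        """(species mask, duplication count) of the clade below x."""
        kids = [y for y in adj[x] if y != frm]
        if not kids:
            return leaf_mask[x], 0
        (m1, d1), (m2, d2) = (down(y, x) for y in kids)
        mask = m1 | m2
        lca, _ = sp.lca(mask)
        l1, _ = sp.lca(m1)
        l2, _ = sp.lca(m2)
        dup = 1 if (lca == l1 or lca == l2) else 0
        return mask, d1 + d2 + dup

    m1, d1 = down(u, v)
    m2, d2 = down(v, u)
    lca, _ = sp.lca(m1 | m2)
    dup = 1 if (lca == sp.lca(m1)[0] or lca == sp.lca(m2)[0]) else 0
    return d1 + d2 + dup


def min_duplications(gene_tree: Phylotree, smap: SpeciesMap,
                     single_rooting: bool = False) -> int:
    """Minimum LCA-reconciliation duplication count.

    By default the count is minimised over all rootings of the gene tree
    (a node is a duplication when its species LCA equals the species LCA
    of one of its children).  ``single_rooting=True`` keeps the rooting of
    the input tree, mirroring reconciliation pipelines that root once.
    """
    sp = _SpeciesIndex(smap.species_tree)
    adj, names = _gene_adjacency(gene_tree)
    unmapped = [n for n in names.values() if n not in smap.mapping]
    if unmapped:
        raise ValueError(f"unmapped gene-tree leaves: {sorted(unmapped)}")
    leaf_mask = {u: sp.leaf_bit[smap.mapping[name]]
                 for u, name in names.items()}
    if single_rooting:
        if not gene_tree.rooted:
            raise ValueError("single_rooting requires a rooted gene tree")
        edges = [_root_edge_of(gene_tree, adj, names)]
    else:
        edges = [(u, v) for u in sorted(adj) for v in adj[u] if u < v]
    return min(_count_dups(adj, names, leaf_mask, sp, e) for e in edges)


def _root_edge_of(gene_tree: Phylotree, adj, names):
    """Locate, in the unrooted adjacency, the edge the input root sat on."""
    left = gene_tree.root.child_nodes()[0]
    left_leaves = {lf.taxon.label for lf in left.leaf_iter()}
    # find the edge splitting left_leaves from the rest
    leaf_of = {u: n for u, n in names.items()}

    def clade(x, frm):
        kids = [y for y in adj[x] if y != frm]
        if not kids:
            return {leaf_of[x]}
        out = set()
        for y in kids:
            out |= clade(y, x)
        return out

    for u in sorted(adj):
        for v in adj[u]:
            if u < v:
                side = clade(u, v)
                if side == left_leaves or side == set(names.values()) - left_leaves:
                    return (u, v)
    raise AssertionError("root edge not found")


def losses_per_branch(rooted_gene_tree: Phylotree, smap: SpeciesMap) -> float:
    """Average LCA-implied gene losses per gene-tree branch.

    For each gene-tree edge from parent u to child c, every species-tree
    edge strictly between M(u) and M(c) implies a lost lineage; a
    duplication at u additionally implies a loss when M(c) lies strictly
    below M(u).  Branch lengths never enter (topology-only criterion).
    """
    if not rooted_gene_tree.rooted:
        raise ValueError("gene tree must be rooted")
    sp = _SpeciesIndex(smap.species_tree)
    dt = rooted_gene_tree.dendropy_tree
    mask: dict = {}
    for nd in dt.postorder_node_iter():
        if nd.is_leaf():
            name = nd.taxon.label
            if name not in smap.mapping:
                raise ValueError(f"unmapped gene-tree leaf: {name!r}")
            mask[id(nd)] = sp.leaf_bit[smap.mapping[name]]
        else:
            kids = nd.child_nodes()
            if len(kids) != 2:
                raise ValueError("gene tree has multifurcations; resolve first")
            mask[id(nd)] = mask[id(kids[0])] | mask[id(kids[1])]
    lca: dict = {k: sp.lca(m) for k, m in mask.items()}
    losses = 0
    n_edges = 0
    for nd in dt.preorder_node_iter():
        if nd.parent_node is None:
            continue
        n_edges += 1
        u = nd.parent_node
        mu, du = lca[id(u)]
        mc, dc = lca[id(nd)]
        kid_lcas = [lca[id(k)][0] for k in u.child_nodes()]
        is_dup = mu in kid_lcas
        skipped = dc - du - 1
        if is_dup:
            skipped += 1
        if skipped > 0:
            losses += skipped
    return losses / n_edges if n_edges else 0.0


# ---------------------------------------------------------------------------
# Alignment accuracy against simulated truth


def _aligned_ordinals(test: Alignment, true: Alignment):
    """Residue-index matrices of both alignments, test reordered to the
    true id order.

    The true alignment must spell the complete sequences; the test
    alignment may be a column-filtered view (its residue provenance,
    tracked through :func:`filterbench.core.apply_mask`, identifies each
    surviving residue).  Residue content is cross-checked against the true
    sequences.
    """
    if set(test.ids) != set(true.ids):
        raise ValueError("alignments contain different sequence ids")
    order = [test.ids.index(name) for name in true.ids]
    ot = test.residue_index()[order]
    orf = true.residue_index()
    true_seqs = true.ungapped()
    rows = [test.rows[k] for k in order]
    for i, row in enumerate(rows):
        seq = true_seqs[i]
        for col, ridx in enumerate(ot[i]):
            if ridx < 0:
                continue
            if ridx >= len(seq) or row[col] != seq[ridx]:
                raise ValueError(
                    "underlying sequences differ between alignments "
                    f"(sequence {true.ids[i]!r})")
    return ot, orf


def sop_scores(test_aln: Alignment, true_aln: Alignment):
    """Per-pair sum-of-pairs statistics.

    Returns (fD, fM, empty_test, empty_true) arrays over unordered sequence
    pairs i<j: fD is correct/test-aligned residue pairs (precision term),
    fM correct/true-aligned (recall term).  Pairs asserting nothing in the
    test alignment take fD = 1 by convention -- no asserted pairs means no
    false assertions -- and are flagged via ``empty_test`` so callers can
    exclude them from averages if desired; symmetrically for fM.
    """
    ot, orf = _aligned_ordinals(test_aln, true_aln)
    n = true_aln.n_seqs
    base = max(int(ot.max(initial=0)), int(orf.max(initial=0))) + 2
    fd, fm, et, er = [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            both_t = (ot[i] >= 0) & (ot[j] >= 0)
            both_r = (orf[i] >= 0) & (orf[j] >= 0)
            t_pairs = ot[i, both_t].astype(np.int64) * base + ot[j, both_t]
            r_pairs = orf[i, both_r].astype(np.int64) * base + orf[j, both_r]
            common = np.intersect1d(t_pairs, r_pairs, assume_unique=True).size
            et.append(t_pairs.size == 0)
            er.append(r_pairs.size == 0)
            fd.append(common / t_pairs.size if t_pairs.size else 1.0)
            fm.append(common / r_pairs.size if r_pairs.size else 1.0)
    return (np.array(fd), np.array(fm),
            np.array(et, dtype=bool), np.array(er, dtype=bool))


def sop_precision(test_aln: Alignment, true_aln: Alignment) -> float:
    """Mean over sequence pairs of the fraction of residue pairs asserted
    by the test alignment that are present in the true alignment."""
    fd, _, _, _ = sop_scores(test_aln, true_aln)
    return float(fd.mean())


def sop_recall(test_aln: Alignment, true_aln: Alignment) -> float:
    """Mean over sequence pairs of the fraction of true residue pairs that
    survive in the test alignment."""
    _, fm, _, _ = sop_scores(test_aln, true_aln)
    return float(fm.mean())


def column_precision_recall(test_aln: Alignment,
                            true_aln: Alignment) -> tuple[float, float]:
    """All-or-nothing column accuracy.

    A test column counts only if its full residue-index column (which
    residue of each sequence, gaps included) is identical to some true
    column.  Precision is the matched fraction of test columns, recall the
    matched fraction of true columns.
    """
    ot, orf = _aligned_ordinals(test_aln, true_aln)
    test_cols = {tuple(ot[:, j]) for j in range(ot.shape[1])}
    true_cols = {tuple(orf[:, j]) for j in range(true_aln.n_cols)}
    matched = test_cols & true_cols
    precision = len(matched) / len(test_cols) if test_cols else 1.0
    recall = len(matched) / len(true_cols) if true_cols else 1.0
    return precision, recall
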