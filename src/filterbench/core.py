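"""Core data model: alignments, column masks, trees, and split comparison.

Alignments are rows of residues over a gap alphabet; column provenance keeps
track of where each current column sat in the original (pre-filter)
alignment, so that masks computed on a filtered alignment can be composed
and reported in original coordinates.  Trees wrap :class:`dendropy.Tree`
with per-branch supports and provide the split (bipartition) comparison and
the support-preserving pruning used by the enriched discordance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
from Bio import SeqIO

GAP = "-"
AA_ALPHABET = "aa"
NT_ALPHABET = "nt"

_ALPHABET_SIZE = {AA_ALPHABET: 20, NT_ALPHABET: 4}


class FormatError(ValueError):
    """Raised for malformed alignment / tree / mask inputs."""


# ---------------------------------------------------------------------------
# Alignment


@dataclass
class Alignment:
    """A multiple sequence alignment over a gap alphabet.

    Residues are stored uppercase; ``.`` and ``?`` are normalised to ``-``
    on construction.  ``col_provenance[j]`` is the 0-based index of current
    column ``j`` in the original alignment the filtering chain started from.
    """

    ids: list[str]
    rows: list[str]
    alphabet: str = AA_ALPHABET
    col_provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate sequence ids")
        self.rows = [_normalise_row(r) for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"ragged rows: lengths {sorted(lengths)}")
        if self.alphabet not in _ALPHABET_SIZE:
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        if self.col_provenance is None:
            self.col_provenance = np.arange(self.n_cols)
        else:
            self.col_provenance = np.asarray(self.col_provenance, dtype=int)
            if len(self.col_provenance) != self.n_cols:
                raise FormatError("col_provenance length != column count")
            if np.any(np.diff(self.col_provenance) <= 0):
                raise FormatError("col_provenance must be strictly increasing")
        # per-residue provenance (index of each residue in the full
        # underlying sequence); set by apply_mask, else derived from rows
        self._residue_index: np.ndarray | None = None

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Residues as a (n_seqs, n_cols) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def ungapped(self) -> list[str]:
        """Rows with gaps stripped (the underlying sequences)."""
        return [r.replace(GAP, "") for r in self.rows]

    def residue_index(self) -> np.ndarray:
        """(n_seqs, n_cols) matrix giving, for each residue, its 0-based
        index in the full underlying sequence; -1 for gaps.

        For an alignment whose rows spell the complete sequences this is
        the running non-gap count; column filtering (:func:`apply_mask`)
        slices the matrix through, so residue identity is preserved even
        though the filtered rows are no longer the complete sequences.
        """
        if self._residue_index is None:
            m = self.matrix()
            nongap = m != GAP
            idx = np.cumsum(nongap, axis=1) - 1
            idx[~nongap] = -1
            self._residue_index = idx
        return self._residue_index


def _normalise_row(row: str) -> str:
    return row.upper().replace(".", GAP).replace("?", GAP)


def read_alignment(path: str | Path, alphabet: str = AA_ALPHABET) -> Alignment:
    """Read an equal-length FASTA file into an :class:`Alignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA (for unaligned sequences)."""
    items = records.items() if isinstance(records, Mapping) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Column masks


class EmptyAlignmentError(ValueError):
    """A mask would remove every column; the family must be excluded."""


@dataclass
class ColumnMask:
    """Boolean keep/drop verdict per column of a specific alignment."""

    keep: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    def __len__(self) -> int:
        return len(self.keep)

    @property
    def fraction_removed(self) -> float:
        if len(self.keep) == 0:
            return 0.0
        return 1.0 - float(self.keep.mean())


def apply_mask(aln: Alignment, mask: ColumnMask) -> Alignment:
    """Keep exactly the columns where ``mask.keep`` is true, composing
    column provenance.  Raises :class:`EmptyAlignmentError` if nothing
    survives, so campaigns can exclude the family."""
    if len(mask) != aln.n_cols:
        raise FormatError(
            f"mask length {len(mask)} != column count {aln.n_cols}")
    idx = np.flatnonzero(mask.keep)
    if idx.size == 0:
        raise EmptyAlignmentError(f"mask {mask.source!r} removes all columns")
    rows = ["".join(r[j] for j in idx) for r in aln.rows]
    out = Alignment(ids=list(aln.ids), rows=rows, alphabet=aln.alphabet,
                    col_provenance=aln.col_provenance[idx])
    out._residue_index = aln.residue_index()[:, idx]
    return out


def column_gap_fraction(aln: Alignment) -> np.ndarray:
    """Per-column fraction of gap characters, in [0, 1]."""
    if aln.n_seqs == 0 or aln.n_cols == 0:
        raise FormatError("empty alignment")
    m = aln.matrix()
    return (m == GAP).mean(axis=0)


def write_mask(mask: ColumnMask, aln: Alignment, path: str | Path) -> None:
    """Serialise a mask as kept 1-based *original*-column indices, one per
    line (composable with provenance from earlier filtering rounds)."""
    kept = aln.col_provenance[mask.keep] + 1
    with open(path, "w") as fh:
        for k in kept:
            fh.write(f"{k}\n")


def read_mask(path: str | Path, aln: Alignment, source: str = "file") -> ColumnMask:
    """Read a kept-index file back into a mask over ``aln``'s columns."""
    with open(path) as fh:
        kept = {int(line) for line in fh if line.strip()}
    keep = np.array([(p + 1) in kept for p in aln.col_provenance], dtype=bool)
    return ColumnMask(keep=keep, source=source)


# ---------------------------------------------------------------------------
# Trees


class Phylotree:
    """A phylogenetic tree with branch lengths and per-branch supports.

    Thin wrapper over :class:`dendropy.Tree`.  The support of the branch
    above a node is stored as ``node.support`` (``None`` if absent); on
    newick round-trips supports live in internal-node labels, following the
    usual convention.  Branch lengths are in PAM or expected substitutions
    per site depending on provenance; the class does not convert units.
    """

    def __init__(self, dtree: dendropy.Tree) -> None:
        self._t = dtree
        for nd in dtree:
            if not hasattr(nd, "support"):
                nd.support = None

    # -- construction ------------------------------------------------------

    @classmethod
    def parse(cls, newick: str) -> "Phylotree":
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True)
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"unparseable newick: {exc}") from exc
        tree = cls(dt)
        for nd in dt.preorder_node_iter():
            if not nd.is_leaf() and nd.label is not None:
                try:
                    nd.support = float(nd.label)
                except ValueError:
                    nd.support = None
        return tree

    @classmethod
    def read(cls, path: str | Path) -> "Phylotree":
        return cls.parse(Path(path).read_text())

    def copy(self) -> "Phylotree":
        return Phylotree.parse(self.to_newick())

    # -- basic accessors ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._t

    @property
    def root(self) -> dendropy.Node:
        return self._t.seed_node

    @property
    def rooted(self) -> bool:
        return len(self.root.child_nodes()) == 2

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self._t.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._t.leaf_node_iter())

    def has_branch_lengths(self) -> bool:
        return all(nd.edge.length is not None
                   for nd in self._t if nd.parent_node is not None)

    def max_root_to_leaf(self) -> float:
        return max(lf.distance_from_root()
                   for lf in self._t.leaf_node_iter())

    def scale_branch_lengths(self, factor: float) -> None:
        for nd in self._t:
            if nd.edge.length is not None:
                nd.edge.length *= factor

    # -- serialisation -----------------------------------------------------

    def to_newick(self) -> str:
        for nd in self._t.preorder_node_iter():
            if not nd.is_leaf():
                nd.label = (None if nd.support is None
                            else repr(float(nd.support)))
        s = self._t.as_string(schema="newick", suppress_rooting=True,
                              unquoted_underscores=True)
        return s.strip() + ("" if s.strip().endswith(";") else ";")

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")

    def __str__(self) -> str:
        return self.to_newick()


def read_tree(path: str | Path) -> Phylotree:
    return Phylotree.read(path)


def write_tree(tree: Phylotree, path: str | Path) -> None:
    tree.write(path)


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitSet:
    """Non-trivial bipartitions of a leaf set, optionally with supports.

    Each split is canonicalised as the frozenset of leaf names on the side
    *not* containing the lexicographically smallest leaf, so complementary
    encodings compare equal.
    """

    leaves: frozenset
    supports: dict  # frozenset -> float | None

    @property
    def splits(self) -> set:
        return set(self.supports)

    def __len__(self) -> int:
        return len(self.supports)

    def __contains__(self, split: frozenset) -> bool:
        return split in self.supports


def splits_of(tree: Phylotree) -> SplitSet:
    """One split per internal branch of the unrooted view of ``tree``.

    The two root-adjacent edges of a rooted tree induce the same
    bipartition; it is recorded once with the larger of the two supports.
    Trees with fewer than 4 leaves have no non-trivial splits.
    """
    leaves = frozenset(tree.leaf_names())
    n = len(leaves)
    out: dict = {}
    if n < 4:
        return SplitSet(leaves=leaves, supports=out)
    ref = min(leaves)
    below: dict = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
    root = tree.root
    for nd in tree.dendropy_tree.preorder_node_iter():
        if nd is root or nd.is_leaf():
            continue
        side = below[nd]
        if ref in side:
            side = leaves - side
        if len(side) < 2 or len(side) > n - 2:
            continue
        sup = nd.support
        if side in out:
            prev = out[side]
            if prev is None or (sup is not None and sup > prev):
                out[side] = sup
        else:
            out[side] = sup
    return SplitSet(leaves=leaves, supports=out)


def fraction_wrong_splits(inferred: Phylotree, reference: Phylotree) -> float:
    """Fraction of inferred splits absent from the reference, normalised by
    the n-3 splits of a fully resolved reference.

    For fully resolved inferred trees this equals the normalised
    Robinson-Foulds distance; unresolved inferred branches count as
    not-wrong (the resolution loss is surfaced by
    :func:`filterbench.assess.support_decomposition`).
    """
    leaves_i = frozenset(inferred.leaf_names())
    leaves_r = frozenset(reference.leaf_names())
    if leaves_i != leaves_r:
        raise ValueError("leaf sets differ between inferred and reference")
    n = len(leaves_r)
    if n < 4:
        raise ValueError("need at least 4 leaves to compare splits")
    wrong = splits_of(inferred).splits - splits_of(reference).splits
    return len(wrong) / (n - 3)


# ---------------------------------------------------------------------------
# Pruning (enriched-test merge rules)


def prune_to_taxa(tree: Phylotree, core_taxa: Iterable[str]) -> Phylotree:
    """Restrict ``tree`` to ``core_taxa``.

    Degree-2 nodes arising from the removal are suppressed; a branch formed
    by merging a path carries the summed branch length and the *maximum* of
    the merged branches' supports (a conservative estimate of the support
    of the merged branch).
    """
    core = set(core_taxa)
    leaf_set = set(tree.leaf_names())
    if not core <= leaf_set:
        raise ValueError(f"core taxa not in tree: {sorted(core - leaf_set)}")
    if len(core) < 4:
        raise ValueError("need at least 4 core taxa")
    t = tree.copy()
    dt = t.dendropy_tree
    # iteratively drop leaves outside the core (internal nodes may become
    # childless and must be dropped too)
    changed = True
    while changed:
        changed = False
        for nd in list(dt.leaf_node_iter()):
            is_core = nd.taxon is not None and nd.taxon.label in core
            if not is_core and nd.parent_node is not None:
                nd.parent_node.remove_child(nd)
                changed = True
    # suppress degree-2 nodes, merging branch lengths (sum) and supports (max)
    changed = True
    while changed:
        changed = False
        for nd in list(dt.preorder_node_iter()):
            kids = nd.child_nodes()
            if nd.parent_node is not None and len(kids) == 1:
                child = kids[0]
                if nd.edge.length is not None or child.edge.length is not None:
                    child.edge.length = ((nd.edge.length or 0.0)
                                         + (child.edge.length or 0.0))
                child.support = _max_support(child.support, nd.support)
                parent = nd.parent_node
                nd.remove_child(child)
                parent.add_child(child)
                parent.remove_child(nd)
                changed = True
        # a root left with a single child: promote the child
        while len(dt.seed_node.child_nodes()) == 1:
            only = dt.seed_node.child_nodes()[0]
            dt.seed_node.remove_child(only)
            only.parent_node = None
            only.edge.length = None
            dt.seed_node = only
            changed = True
    return Phylotree(dt)


def _max_support(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return max(a, b)
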