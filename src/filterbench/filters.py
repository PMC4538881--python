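"""Alignment column filters.

Two baselines (random column removal, gappiest-column removal),
re-implemented variants of published trimming algorithms (a Gblocks-like
block filter, a TrimAl-gappyout-like gradient filter, a BMGE-like
sliding-window entropy filter), and an adapter for external trimming tools.
Every filter is a pure function of (alignment, parameters, seed) returning
a :class:`~filterbench.core.ColumnMask`.

The "-like" variants follow the published descriptions of the algorithms,
not the binaries byte-for-byte; where the descriptions omit numeric class
boundaries the conventions of the original tools are adopted and exposed as
parameters (see docs/methods.md).
"""

from __future__ import annotations

import math
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .core import (Alignment, ColumnMask, GAP, column_gap_fraction,
                   read_alignment, write_alignment)

__all__ = [
    "FilterSpec", "filter_random", "filter_max_gap", "filter_gblocks_like",
    "filter_gappyout", "filter_entropy", "run_external_filter",
    "GBLOCKS_RELAXED", "make_filter", "BUILTIN_FILTERS",
]


def _round_half_away(x: float) -> int:
    """round(x) with halves away from zero (documented rounding rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


# ---------------------------------------------------------------------------
# Baselines


def filter_random(aln: Alignment, fraction: float,
                  seed: int | np.random.Generator = 0) -> ColumnMask:
    """Drop exactly round(fraction * ncol) columns uniformly at random."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ncol = aln.n_cols
    k = _round_half_away(fraction * ncol)
    keep = np.ones(ncol, dtype=bool)
    drop = rng.choice(ncol, size=k, replace=False)
    keep[drop] = False
    return ColumnMask(keep, source=f"random(fraction={fraction})")


def filter_max_gap(aln: Alignment, fraction: float) -> ColumnMask:
    """Drop the round(fraction * ncol) columns with the most gaps.

    Ties on gap fraction are broken by preferring to drop the rightmost
    column, which makes the mask deterministic.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    ncol = aln.n_cols
    k = _round_half_away(fraction * ncol)
    gf = column_gap_fraction(aln)
    # sort by (gap fraction desc, column index desc); drop the first k
    order = np.lexsort((-np.arange(ncol), -gf))
    keep = np.ones(ncol, dtype=bool)
    keep[order[:k]] = False
    return ColumnMask(keep, source=f"maxgap(fraction={fraction})")


# ---------------------------------------------------------------------------
# Gblocks-like block filter


#: the "relaxed" parameterisation described for Gblocks
GBLOCKS_RELAXED = dict(min_flank_seqs=9, max_contig_noncons=10,
                       min_block1=5, min_block2=5, gap_policy="with half")


def filter_gblocks_like(aln: Alignment,
                        min_cons_seqs: Optional[int] = None,
                        min_flank_seqs: Optional[int] = None,
                        max_contig_noncons: int = 8,
                        min_block1: int = 15,
                        min_block2: int = 10,
                        gap_policy: str = "none") -> ColumnMask:
    """Block-based filter following the Gblocks algorithm description.

    Steps, in order: (1) classify each column as nonconserved, conserved or
    highly conserved from the count of identical residues and the gap
    policy; (2) remove runs of more than ``max_contig_noncons`` contiguous
    nonconserved columns; (3) trim every remaining block to highly
    conserved flanks; (4) remove blocks shorter than ``min_block1``;
    (5) remove gap positions disallowed by ``gap_policy`` together with
    their adjacent nonconserved stretches; (6) remove blocks shorter than
    ``min_block2``.

    Defaults follow the original tool's conventions: a column is conserved
    when its majority residue occurs in more than N/2 sequences
    (``min_cons_seqs`` = floor(N/2)+1), highly conserved at >= 0.85 N
    (``min_flank_seqs``), and with ``gap_policy="none"`` any gap makes a
    column nonconserved.  ``gap_policy`` may be "none", "with half"
    (columns with gaps in more than half of the sequences are disallowed)
    or "all" (gaps ignored).
    """
    if gap_policy not in ("none", "with half", "all"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = aln.n_seqs
    ncol = aln.n_cols
    if min_cons_seqs is None:
        min_cons_seqs = n // 2 + 1
    if min_flank_seqs is None:
        min_flank_seqs = math.ceil(0.85 * n)

    m = aln.matrix()
    is_gap = m == GAP
    gap_counts = is_gap.sum(axis=0)
    max_ident = np.zeros(ncol, dtype=int)
    for j in range(ncol):
        col = m[~is_gap[:, j], j]
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            max_ident[j] = counts.max()

    if gap_policy == "none":
        gap_disallowed = gap_counts > 0
    elif gap_policy == "with half":
        gap_disallowed = gap_counts > n / 2
    else:
        gap_disallowed = np.zeros(ncol, dtype=bool)

    conserved = (max_ident >= min_cons_seqs) & ~gap_disallowed
    highly = (max_ident >= min_flank_seqs) & ~gap_disallowed
    noncons = ~conserved & ~highly

    keep = np.ones(ncol, dtype=bool)
    # (2) long nonconserved stretches
    for start, end in _runs(noncons):
        if end - start > max_contig_noncons:
            keep[start:end] = False
    # (3) trim blocks to highly conserved flanks
    for start, end in _runs(keep):
        block = np.arange(start, end)
        flank = np.flatnonzero(highly[block])
        if flank.size == 0:
            keep[start:end] = False
        else:
            keep[start:start + flank[0]] = False
            keep[start + flank[-1] + 1:end] = False
    # (4) short blocks, first round
    _drop_short_blocks(keep, min_block1)
    # (5) disallowed gap positions and adjacent nonconserved stretches
    for j in np.flatnonzero(gap_disallowed & keep):
        keep[j] = False
        for step in (-1, 1):
            i = j + step
            while 0 <= i < ncol and keep[i] and noncons[i]:
                keep[i] = False
                i += step
    # (6) short blocks, second round
    _drop_short_blocks(keep, min_block2)
    return ColumnMask(keep, source=(
        f"gblocks_like(cons={min_cons_seqs},flank={min_flank_seqs},"
        f"noncons={max_contig_noncons},b1={min_block1},b2={min_block2},"
        f"gaps={gap_policy!r})"))


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs."""
    j = 0
    n = len(mask)
    while j < n:
        if mask[j]:
            start = j
            while j < n and mask[j]:
                j += 1
            yield start, j
        else:
            j += 1


def _drop_short_blocks(keep: np.ndarray, min_len: int) -> None:
    for start, end in list(_runs(keep)):
        if end - start < min_len:
            keep[start:end] = False


# ---------------------------------------------------------------------------
# TrimAl gappyout-like filter


def filter_gappyout(aln: Alignment) -> ColumnMask:
    """Gap-threshold filter with an automatically selected threshold.

    The candidate thresholds are the distinct column gap fractions.  For
    each, the proportion of columns removed (those with gap fraction
    strictly above the threshold) defines a nonincreasing curve; the
    threshold at the greatest discrete drop of that curve is selected, with
    ties resolved toward the smaller threshold (removing more columns).
    A flat curve (gapless or uniform gappiness) keeps everything.
    """
    gf = column_gap_fraction(aln)
    ncol = len(gf)
    thresholds = np.unique(gf)
    if len(thresholds) < 2:
        return ColumnMask(np.ones(ncol, dtype=bool), source="gappyout")
    removed = np.array([(gf > th).mean() for th in thresholds])
    grad = removed[:-1] - removed[1:]
    best = int(np.argmax(grad))  # argmax takes the first (smallest) tie
    threshold = thresholds[best]
    keep = gf <= threshold
    return ColumnMask(keep, source=f"gappyout(threshold={threshold:.4g})")


# ---------------------------------------------------------------------------
# BMGE-like entropy filter


def filter_entropy(aln: Alignment, window: int = 3,
                   cutoff: float = 0.5) -> ColumnMask:
    """Sliding-window entropy filter.

    Each column gets the Shannon entropy of its non-gap residues normalised
    by log(alphabet size); gap-only columns score 1.0 (always removable).
    Scores are smoothed by a centred moving average of odd width ``window``
    (truncated at the alignment edges) and columns with smoothed score
    strictly above ``cutoff`` are dropped.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    from .core import _ALPHABET_SIZE
    k = _ALPHABET_SIZE[aln.alphabet]
    m = aln.matrix()
    ncol = aln.n_cols
    ent = np.empty(ncol)
    for j in range(ncol):
        col = m[:, j]
        col = col[col != GAP]
        if col.size == 0:
            ent[j] = 1.0
            continue
        _, counts = np.unique(col, return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log(p)).sum()
        ent[j] = h / np.log(k)
    half = window // 2
    smoothed = np.array([ent[max(0, j - half):j + half + 1].mean()
                         for j in range(ncol)])
    keep = smoothed <= cutoff
    return ColumnMask(keep, source=f"entropy(window={window},cutoff={cutoff})")


# ---------------------------------------------------------------------------
# External tool adapter


@dataclass
class FilterSpec:
    """Description of a filter invocation (built-in or external tool)."""

    name: str
    parameters: dict = field(default_factory=dict)
    executable: Optional[str] = None
    arg_template: Optional[list] = None   # tokens; {input}/{output} expanded
    output_parser: str = "trimmed_fasta"  # or "kept_indices"


class ToolError(RuntimeError):
    pass


def run_external_filter(aln: Alignment, spec: FilterSpec,
                        workdir: str | Path) -> ColumnMask:
    """Run an external trimming tool and map its output to a column mask.

    The alignment is written to ``workdir``, the tool invoked with its
    argument template ({input} and {output} placeholders expanded), and the
    result parsed either as a file of kept 1-based column indices
    (``output_parser="kept_indices"``) or as a trimmed FASTA whose columns
    are matched back to the original alignment in order
    (``output_parser="trimmed_fasta"``).
    """
    if spec.executable is None or spec.arg_template is None:
        raise ToolError(f"filter {spec.name!r} has no executable configured")
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    inp = work / "input.fasta"
    outp = work / "output"
    write_alignment(aln, inp)
    argv = [spec.executable] + [
        tok.format(input=str(inp), output=str(outp))
        for tok in spec.arg_template]
    proc = subprocess.run(argv, capture_output=True, text=True)
    (work / "command.log").write_text(
        f"argv: {argv}\nexit: {proc.returncode}\nstderr:\n{proc.stderr}\n")
    if proc.returncode != 0:
        raise ToolError(
            f"{spec.name} exited {proc.returncode}: {proc.stderr.strip()}")
    if spec.output_parser == "kept_indices":
        kept = sorted(int(line) for line in outp.read_text().split()
                      if line.strip())
        keep = np.zeros(aln.n_cols, dtype=bool)
        for k in kept:
            if not 1 <= k <= aln.n_cols:
                raise ToolError(f"kept index {k} out of range")
            keep[k - 1] = True
    elif spec.output_parser == "trimmed_fasta":
        trimmed = read_alignment(outp, alphabet=aln.alphabet)
        keep = _match_columns(aln, trimmed)
    else:
        raise ToolError(f"unknown output parser {spec.output_parser!r}")
    return ColumnMask(keep, source=f"external:{spec.name}")


def _match_columns(aln: Alignment, trimmed: Alignment) -> np.ndarray:
    """Greedy in-order matching of trimmed columns to original columns."""
    if trimmed.ids != aln.ids:
        order = {name: i for i, name in enumerate(trimmed.ids)}
        if set(trimmed.ids) != set(aln.ids):
            raise ToolError("trimmed output has different sequence ids")
        trimmed = Alignment(
            ids=list(aln.ids),
            rows=[trimmed.rows[order[name]] for name in aln.ids],
            alphabet=aln.alphabet)
    keep = np.zeros(aln.n_cols, dtype=bool)
    j = 0
    for tj in range(trimmed.n_cols):
        target = trimmed.column(tj)
        while j < aln.n_cols and aln.column(j) != target:
            j += 1
        if j == aln.n_cols:
            raise ToolError(
                f"trimmed column {tj} cannot be mapped to the input")
        keep[j] = True
        j += 1
    return keep


# ---------------------------------------------------------------------------
# Registry


BUILTIN_FILTERS = {
    "unfiltered": lambda aln, **kw: ColumnMask(
        np.ones(aln.n_cols, dtype=bool), source="unfiltered"),
    "random": filter_random,
    "maxgap": filter_max_gap,
    "gblockslike": filter_gblocks_like,
    "gappyout": filter_gappyout,
    "entropy": filter_entropy,
}


def make_filter(name: str, params: Optional[dict] = None,
                seed: Optional[int] = None) -> Callable[[Alignment], ColumnMask]:
    """Bind a registered filter name and parameters into ``aln -> mask``."""
    params = dict(params or {})
    if name not in BUILTIN_FILTERS:
        raise KeyError(f"unknown filter {name!r}; "
                       f"choose from {sorted(BUILTIN_FILTERS)}")
    fn = BUILTIN_FILTERS[name]
    if name == "random" and seed is not None:
        params.setdefault("seed", seed)

    def bound(aln: Alignment) -> ColumnMask:
        return fn(aln, **params)

    return bound
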