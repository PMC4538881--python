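"""Distance-based tree inference with branch supports.

The built-in pathway is: maximum-likelihood pairwise distances under the
WAG model (PAM units) -> neighbor-joining topology -> optional
variance-weighted least-squares refinement with nearest-neighbor
interchanges.  Supports come either from column bootstrap (split
frequencies) or from a branch-length threshold; adapters allow external ML
tools to stand in for the built-in pathway.
"""

from __future__ import annotations

import subprocess
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import skbio
from scipy.optimize import nnls

from . import _wag
from .core import Alignment, GAP, Phylotree, splits_of, write_alignment

__all__ = [
    "DistanceMatrix", "pairwise_distances", "nj_tree", "wls_nni_tree",
    "bootstrap_support", "branch_length_support", "TreeToolSpec",
    "run_external_tree", "wls_loss",
]

#: bracket for the pairwise ML distance search, PAM
_D_MIN, _D_MAX = 1e-8, 1000.0


@dataclass
class DistanceMatrix:
    """Pairwise evolutionary distances with variance estimates.

    ``units`` is "pam" for amino-acid ML distances and "subst/site" for
    nucleotide distances; downstream tree construction is unit-agnostic.
    """

    taxa: list[str]
    d: np.ndarray
    v: np.ndarray
    units: str = "pam"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n) or self.v.shape != (n, n):
            raise ValueError("matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")

    @property
    def n(self) -> int:
        return len(self.taxa)


def _encode(aln: Alignment) -> np.ndarray:
    """Rows as integer codes in WAG order; gaps/non-standard -> -1."""
    lookup = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(_wag.AA_ORDER):
        lookup[ord(ch)] = i
    arr = np.frombuffer("".join(aln.rows).encode(), dtype=np.uint8)
    return lookup[arr].reshape(aln.n_seqs, aln.n_cols)


def pairwise_distances(aln: Alignment, model: str = "wag",
                       var_floor: float = 1e-4) -> DistanceMatrix:
    """ML pairwise distances on pairwise shared (both non-gap) sites.

    For amino acids the distance maximises the WAG likelihood by bracketed
    scalar search on [1e-8, 1000] PAM (relative tolerance 1e-6); saturated
    pairs are capped at the upper bound with a warning.  For nucleotides
    the Jukes-Cantor correction is used.  Variances follow v ~ d^2 with a
    small floor (``var_floor``, same units as d), which downstream
    weighted least squares uses as relative weights.
    """
    n = aln.n_seqs
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if aln.alphabet == "aa" and model.lower() == "wag":
        d = _wag_ml_distances(aln)
        units = "pam"
    elif aln.alphabet == "nt" or model.lower() == "jc":
        d = _jc_distances(aln)
        units = "subst/site"
    else:
        raise ValueError(f"unsupported model {model!r} for {aln.alphabet}")
    v = np.maximum(d, var_floor) ** 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(taxa=list(aln.ids), d=d, v=v, units=units)


def _wag_ml_distances(aln: Alignment) -> np.ndarray:
    model = _wag.wag_model()
    codes = _encode(aln)
    n = aln.n_seqs
    onehot = np.zeros((n, aln.n_cols, _wag.N_AA))
    valid = codes >= 0
    idx = np.nonzero(valid)
    onehot[idx[0], idx[1], codes[idx]] = 1.0
    # substitution-pair counts via one BLAS call: stack the one-hot rows as
    # (n*20, L) and read 20x20 blocks out of the Gram matrix
    x = onehot.transpose(0, 2, 1).reshape(n * _wag.N_AA, aln.n_cols)
    gram = x @ x.T
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    k = _wag.N_AA
    c = np.array([gram[i * k:(i + 1) * k, j * k:(j + 1) * k]
                  for i, j in pairs])
    shared = c.sum(axis=(1, 2))
    if np.any(shared < 1):
        i, j = pairs[int(np.argmin(shared))]
        raise ValueError(
            f"no shared non-gap sites between {aln.ids[i]!r} and {aln.ids[j]!r}")
    diffs = c.sum(axis=(1, 2)) - np.einsum("paa->p", c)
    dist = _ml_distance_from_counts(c, model)
    dist[diffs == 0] = 0.0
    d = np.zeros((n, n))
    for (i, j), val in zip(pairs, dist):
        d[i, j] = d[j, i] = val
    return d


def _ml_distance_from_counts(c: np.ndarray, model: _wag.WagModel) -> np.ndarray:
    """Vectorised bracketed search for the ML distance of each count matrix."""

    cflat = c.reshape(len(c), -1)

    def loglik(d_pam: np.ndarray) -> np.ndarray:
        p = model.transition_matrices(d_pam * _wag.SUBS_PER_PAM)
        return np.einsum("pab,pab->p", c, np.log(p))

    def loglik_scalar(d_pam: float) -> np.ndarray:
        p = model.transition_matrix(d_pam * _wag.SUBS_PER_PAM)
        return cflat @ np.log(p).ravel()

    grid = np.geomspace(_D_MIN, _D_MAX, 61)
    ll = np.stack([loglik_scalar(g) for g in grid], axis=1)
    best = np.argmax(ll, axis=1)
    lo = grid[np.maximum(best - 1, 0)]
    hi = grid[np.minimum(best + 1, len(grid) - 1)]
    # golden-section maximisation, vectorised over pairs
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    for _ in range(60):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        f1, f2 = loglik(x1), loglik(x2)
        a = np.where(f1 < f2, x1, a)
        b = np.where(f1 < f2, b, x2)
        if np.all((b - a) <= 1e-6 * np.maximum(b, 1.0)):
            break
    d = (a + b) / 2.0
    if np.any(d >= _D_MAX * 0.999):
        warnings.warn("saturated pair(s) capped at 1000 PAM")
        d = np.minimum(d, _D_MAX)
    return d


def _jc_distances(aln: Alignment) -> np.ndarray:
    m = aln.matrix()
    n = aln.n_seqs
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] != GAP) & (m[j] != GAP)
            if not ok.any():
                raise ValueError(
                    f"no shared non-gap sites between {aln.ids[i]!r} "
                    f"and {aln.ids[j]!r}")
            p = float((m[i, ok] != m[j, ok]).mean())
            if p >= 0.75:
                warnings.warn("saturated pair capped")
                val = _D_MAX * _wag.SUBS_PER_PAM
            else:
                val = -0.75 * np.log1p(-4.0 * p / 3.0)
            d[i, j] = d[j, i] = val
    return d


# ---------------------------------------------------------------------------
# Neighbor joining (delegated to scikit-bio; negatives clamped to zero)


def nj_tree(dm: DistanceMatrix) -> Phylotree:
    """Standard neighbor-joining topology with branch lengths; negative
    branch lengths are clamped to zero."""
    if dm.n < 3:
        raise ValueError("need at least 3 taxa")
    sk = skbio.DistanceMatrix(dm.d, ids=dm.taxa)
    tr = skbio.tree.nj(sk, neg_as_zero=True)
    return Phylotree.parse(str(tr))


# ---------------------------------------------------------------------------
# Weighted least-squares with NNI search


class _UTree:
    """Unrooted binary tree as an adjacency structure for NNI search."""

    def __init__(self, adj: dict, names: dict) -> None:
        self.adj = adj          # node -> sorted list of neighbours
        self.names = names      # leaf node -> taxon name

    @classmethod
    def from_phylotree(cls, tree: Phylotree) -> "_UTree":
        adj: dict = {}
        names: dict = {}
        node_id: dict = {}

        def nid(nd):
            if id(nd) not in node_id:
                node_id[id(nd)] = len(node_id)
                adj[node_id[id(nd)]] = []
            return node_id[id(nd)]

        for nd in tree.dendropy_tree.preorder_node_iter():
            u = nid(nd)
            if nd.is_leaf():
                names[u] = nd.taxon.label
            if nd.parent_node is not None:
                v = nid(nd.parent_node)
                adj[u].append(v)
                adj[v].append(u)
        # suppress a degree-2 root so the tree is properly unrooted
        for u in list(adj):
            if len(adj[u]) == 2 and u not in names:
                a, b = adj[u]
                adj[a] = [x for x in adj[a] if x != u] + [b]
                adj[b] = [x for x in adj[b] if x != u] + [a]
                del adj[u]
        return cls(adj, names)

    def edges(self) -> list:
        out = []
        for u in sorted(self.adj):
            for v in self.adj[u]:
                if u < v:
                    out.append((u, v))
        return out

    def internal_edges(self) -> list:
        return [(u, v) for u, v in self.edges()
                if u not in self.names and v not in self.names]

    def leaf_nodes(self) -> list:
        return sorted(self.names)

    def paths(self):
        """Edge index matrix A over leaf pairs, plus the pair list."""
        edges = self.edges()
        eidx = {frozenset(e): k for k, e in enumerate(edges)}
        leaves = self.leaf_nodes()
        # parents via BFS from an arbitrary anchor
        anchor = leaves[0]
        parent = {anchor: None}
        stack = [anchor]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        depth = {}
        for u in parent:
            dpt, x = 0, u
            while parent[x] is not None:
                x = parent[x]
                dpt += 1
            depth[u] = dpt
        pairs = [(leaves[i], leaves[j]) for i in range(len(leaves))
                 for j in range(i + 1, len(leaves))]
        a = np.zeros((len(pairs), len(edges)))
        for p, (x, y) in enumerate(pairs):
            while x != y:
                if depth[x] < depth[y]:
                    x, y = y, x
                a[p, eidx[frozenset((x, parent[x]))]] = 1.0
                x = parent[x]
        return a, pairs, edges

    def nni_alternatives(self, edge: tuple):
        """The two topologies one NNI away across an internal edge.

        Yields (swap_a, swap_b) node pairs; applying a swap exchanges the
        subtrees hanging off the two endpoints.
        """
        u, v = edge
        nu = sorted(x for x in self.adj[u] if x != v)
        nv = sorted(x for x in self.adj[v] if x != u)
        yield (nu[1], nv[0])
        yield (nu[1], nv[1])

    def swap(self, edge: tuple, move: tuple) -> None:
        u, v = edge
        a, b = move    # a attached to u, b attached to v
        self.adj[u] = sorted(x for x in self.adj[u] if x != a) + [b]
        self.adj[v] = sorted(x for x in self.adj[v] if x != b) + [a]
        self.adj[a] = sorted(x for x in self.adj[a] if x != u) + [v]
        self.adj[b] = sorted(x for x in self.adj[b] if x != v) + [u]

    def to_phylotree(self, lengths: Optional[dict] = None) -> Phylotree:
        """Render as newick, rooted at the internal node next to the first
        leaf (trifurcating root: the standard unrooted representation)."""
        leaves = self.leaf_nodes()
        root = next(x for x in self.adj[leaves[0]])

        def render(u, frm) -> str:
            kids = [x for x in self.adj[u] if x != frm]
            length = ""
            if lengths is not None and frm is not None:
                length = f":{lengths[frozenset((u, frm))]:.10g}"
            if u in self.names:
                return f"{self.names[u]}{length}"
            inner = ",".join(render(x, u) for x in kids)
            return f"({inner}){length}"

        return Phylotree.parse(f"{render(root, None)};")


def wls_loss(tree_or_utree, dm: DistanceMatrix):
    """Weighted least-squares fit of branch lengths on a fixed topology.

    Returns (loss, lengths) where lengths maps frozenset edges to
    nonnegative fitted branch lengths and loss is
    sum_ij (d_ij - p_ij)^2 / v_ij.
    """
    ut = (tree_or_utree if isinstance(tree_or_utree, _UTree)
          else _UTree.from_phylotree(tree_or_utree))
    a, pairs, edges = ut.paths()
    tx = {name: k for k, name in enumerate(dm.taxa)}
    dvec = np.array([dm.d[tx[ut.names[x]], tx[ut.names[y]]] for x, y in pairs])
    vvec = np.array([dm.v[tx[ut.names[x]], tx[ut.names[y]]] for x, y in pairs])
    w = 1.0 / np.maximum(vvec, 1e-12)
    sw = np.sqrt(w)
    x, _ = nnls(a * sw[:, None], dvec * sw)
    resid = dvec - a @ x
    loss = float(np.sum(w * resid ** 2))
    lengths = {frozenset(e): x[k] for k, e in enumerate(edges)}
    return loss, lengths


def wls_nni_tree(dm: DistanceMatrix,
                 start: Optional[Phylotree] = None) -> Phylotree:
    """Hill-climb the weighted least-squares loss over NNI moves.

    Starts from neighbor joining unless ``start`` is given; sweeps internal
    edges in a deterministic order with first-improvement acceptance and
    re-sweeps until a full pass makes no change.  Branch lengths are fitted
    by nonnegative weighted least squares.
    """
    if start is None:
        start = nj_tree(dm)
    ut = _UTree.from_phylotree(start)
    if set(ut.names.values()) != set(dm.taxa):
        raise ValueError("start tree taxa differ from distance matrix")
    loss, lengths = wls_loss(ut, dm)
    improved = True
    while improved:
        improved = False
        for edge in ut.internal_edges():
            if frozenset(edge) not in {frozenset(e) for e in ut.edges()}:
                continue  # topology changed earlier in this sweep
            for move in list(ut.nni_alternatives(edge)):
                ut.swap(edge, move)
                new_loss, new_lengths = wls_loss(ut, dm)
                if new_loss < loss - 1e-12:
                    loss, lengths = new_loss, new_lengths
                    improved = True
                    break
                ut.swap(edge, (move[1], move[0]))  # undo
            if improved:
                break
    return ut.to_phylotree(lengths)


# ---------------------------------------------------------------------------
# Branch supports


def bootstrap_support(aln: Alignment,
                      builder: Callable[[Alignment], Phylotree],
                      n_reps: int = 100,
                      seed: int | np.random.Generator = 0) -> Phylotree:
    """Column-bootstrap supports: split frequencies over ``n_reps``
    replicate trees, attached to the tree built from the full alignment."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    main = builder(aln)
    counts: dict = {}
    for _ in range(n_reps):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rows = ["".join(r[j] for j in cols) for r in aln.rows]
        rep_aln = Alignment(ids=list(aln.ids), rows=rows,
                            alphabet=aln.alphabet)
        rep = builder(rep_aln)
        for split in splits_of(rep).splits:
            counts[split] = counts.get(split, 0) + 1
    _attach_supports(main, {s: c / n_reps for s, c in counts.items()})
    return main


def _attach_supports(tree: Phylotree, freq: dict) -> None:
    leaves = frozenset(tree.leaf_names())
    ref = min(leaves)
    below: dict = {}
    for nd in tree.dendropy_tree.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = frozenset([nd.taxon.label])
        else:
            below[nd] = frozenset().union(*(below[c] for c in nd.child_nodes()))
            if nd.parent_node is None:
                continue
            side = below[nd]
            if ref in side:
                side = leaves - side
            if 2 <= len(side) <= len(leaves) - 2:
                nd.support = freq.get(side, 0.0)


def branch_length_support(tree: Phylotree, threshold_pam: float) -> Phylotree:
    """Branch-length surrogate for support: internal branches shorter than
    ``threshold_pam`` are flagged unresolved (support 0), branches of at
    least the threshold resolved (support 1)."""
    t = tree.copy()
    for nd in t.dendropy_tree.preorder_node_iter():
        if nd.is_leaf() or nd.parent_node is None:
            continue
        if nd.edge.length is None:
            raise ValueError("tree has internal branches without lengths")
        nd.support = 1.0 if nd.edge.length >= threshold_pam else 0.0
    return t


# ---------------------------------------------------------------------------
# External ML tool adapter


@dataclass
class TreeToolSpec:
    name: str
    executable: str
    arg_template: list = field(default_factory=list)
    output_suffix: str = ".nwk"   # {output} placeholder target


class ToolError(RuntimeError):
    pass


def run_external_tree(aln: Alignment, toolspec: TreeToolSpec,
                      workdir: str | Path) -> Phylotree:
    """Invoke an external tree program on the alignment and parse its
    newick output (supports read from internal-node labels)."""
    work = Path(workdir)
    work.mkdir(parents=True, exist_ok=True)
    inp = work / "input.fasta"
    outp = work / ("output" + toolspec.output_suffix)
    write_alignment(aln, inp)
    argv = [toolspec.executable] + [
        tok.format(input=str(inp), output=str(outp))
        for tok in toolspec.arg_template]
    proc = subprocess.run(argv, capture_output=True, text=True)
    (work / "command.log").write_text(
        f"argv: {argv}\nexit: {proc.returncode}\nstderr:\n{proc.stderr}\n")
    if proc.returncode != 0:
        raise ToolError(
            f"{toolspec.name} exited {proc.returncode}: {proc.stderr.strip()}")
    text = outp.read_text() if outp.exists() else proc.stdout
    tree = Phylotree.parse(text)
    if set(tree.leaf_names()) != set(aln.ids):
        raise ToolError("output tree leaves differ from alignment ids")
    return tree
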