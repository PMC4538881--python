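"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own tree/alignment machinery:
trees are plain adjacency dicts, splits are computed by direct set
partitioning, and reconciliation is done with explicit set-based LCA
walks, so they can serve as independent checks of the implementation.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------------------
# Unrooted binary topology enumeration (adjacency-based)


def enumerate_unrooted(leaves):
    """All unrooted binary topologies on the given leaves as adjacency
    dicts (leaf nodes are the labels themselves, internal nodes ints).
    3 leaves -> 1 topology, 6 -> 105, 7 -> 945."""
    leaves = list(leaves)
    assert len(leaves) >= 3
    first = {0: leaves[:3]}
    for lf in leaves[:3]:
        first[lf] = [0]
    trees = [first]
    next_internal = 1
    for lf in leaves[3:]:
        new_trees = []
        for adj in trees:
            for u, v in _edges(adj):
                t = {k: list(vs) for k, vs in adj.items()}
                w = next_internal
                t[u] = [x if x != v else w for x in t[u]]
                t[v] = [x if x != u else w for x in t[v]]
                t[w] = [u, v, lf]
                t[lf] = [w]
                new_trees.append(t)
        trees = new_trees
        next_internal += 1
    return trees


def _edges(adj):
    seen = set()
    for u, vs in adj.items():
        for v in vs:
            key = frozenset((str(u), str(v)))
            if key not in seen:
                seen.add(key)
                yield u, v


def splits_of_adjacency(adj, leaves):
    """Non-trivial splits as canonical frozensets (side without min leaf)."""
    leaves = set(leaves)
    ref = min(leaves)
    out = set()
    for u, v in _edges(adj):
        side = _leaves_beyond(adj, u, v, leaves)
        if ref in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(frozenset(side))
    return out


def _leaves_beyond(adj, u, v, leaves):
    """Leaves reachable from v without passing through u."""
    stack, seen = [v], {u, v}
    found = set()
    while stack:
        x = stack.pop()
        if x in leaves:
            found.add(x)
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return found


def adjacency_to_newick(adj, leaves):
    """Render an adjacency tree as newick (rooted at an internal node)."""
    leaves = set(leaves)
    root = next(u for u in adj if u not in leaves)

    def render(u, frm):
        kids = [x for x in adj[u] if x != frm]
        if u in leaves:
            return str(u)
        return "(" + ",".join(render(x, u) for x in kids) + ")"

    return render(root, None) + ";"


# ---------------------------------------------------------------------------
# Brute-force duplication counting (set-based LCA, all rootings)


def brute_min_duplications(adj, leaves, gene_to_species, species_newick_sets):
    """Minimum duplications over all rootings by direct recursion.

    ``species_newick_sets`` is the species tree given as a list of clades
    (sets of species), root first; the LCA of a species set is the
    smallest clade containing it.
    """

    def lca(spset):
        best = None
        for clade in species_newick_sets:
            if spset <= clade and (best is None or len(clade) < len(best)):
                best = clade
        return frozenset(best)

    def count(u, frm):
        kids = [x for x in adj[u] if x != frm]
        if not kids:
            return {gene_to_species[u]}, 0
        (s1, d1), (s2, d2) = (count(x, u) for x in kids)
        spset = s1 | s2
        me = lca(spset)
        dup = 1 if me in (lca(s1), lca(s2)) else 0
        return spset, d1 + d2 + dup

    best = None
    for u, v in _edges(adj):
        s1, d1 = count(u, v)
        s2, d2 = count(v, u)
        me = lca(s1 | s2)
        dup = 1 if me in (lca(s1), lca(s2)) else 0
        total = d1 + d2 + dup
        if best is None or total < best:
            best = total
    return best


def species_clades(nested):
    """Clades (sets of leaf labels) of a species tree given as nested
    tuples, root clade first."""
    out = []

    def walk(node):
        if isinstance(node, tuple):
            members = set()
            for child in node:
                members |= walk(child)
            out.append(members)
            return members
        out.append({node})
        return {node}

    walk(nested)
    out.sort(key=len, reverse=True)
    return out


# ---------------------------------------------------------------------------
# Pair-enumeration oracle for sum-of-pairs scores


def homology_pairs(rows):
    """All aligned residue pairs of an alignment given as gapped rows:
    {(i, j, ordinal_i, ordinal_j)} for every column where rows i and j
    both have residues, ordinals counted within each ungapped row."""
    n = len(rows)
    ncols = len(rows[0])
    ords = []
    for r in rows:
        o, k = [], 0
        for ch in r:
            if ch == "-":
                o.append(-1)
            else:
                o.append(k)
                k += 1
        ords.append(o)
    pairs = set()
    for i, j in itertools.combinations(range(n), 2):
        for c in range(ncols):
            if ords[i][c] >= 0 and ords[j][c] >= 0:
                pairs.add((i, j, ords[i][c], ords[j][c]))
    return pairs


def surviving_pairs(rows, kept_cols):
    """Aligned residue pairs restricted to a subset of columns, with
    ordinals still counted in the *full* rows (residue identity is that of
    the complete sequences)."""
    n = len(rows)
    kept = set(kept_cols)
    ords = []
    for r in rows:
        o, k = [], 0
        for ch in r:
            if ch == "-":
                o.append(-1)
            else:
                o.append(k)
                k += 1
        ords.append(o)
    pairs = set()
    for i, j in itertools.combinations(range(n), 2):
        for c in kept:
            if ords[i][c] >= 0 and ords[j][c] >= 0:
                pairs.add((i, j, ords[i][c], ords[j][c]))
    return pairs
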