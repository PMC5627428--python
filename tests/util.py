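"""Independent reference implementations ("oracles") and tree enumerators.

Everything here works on a plain nested-tuple tree representation — a leaf
is a string, an internal node a tuple of subtrees — deliberately sharing no
code or data structures with famkit, so the oracles stay independent of
the implementations they check.
"""

from __future__ import annotations

from famkit.treecore import Node, PhyloTree

# ---------------------------------------------------------------------------
# nested-tuple trees
# ---------------------------------------------------------------------------


def tuple_to_tree(tp) -> PhyloTree:
    """Convert a nested-tuple tree to a famkit PhyloTree (no lengths)."""

    def rec(t):
        if isinstance(t, str):
            return Node(label=t)
        nd = Node()
        for c in t:
            nd.add_child(rec(c))
        return nd

    return PhyloTree(rec(tp))


def tuple_leaves(tp) -> frozenset:
    if isinstance(tp, str):
        return frozenset({tp})
    out = frozenset()
    for c in tp:
        out |= tuple_leaves(c)
    return out


def _positions(tp):
    """All child-slot paths in a tuple tree (each path names one edge)."""
    for i, c in enumerate(tp):
        yield (i,)
        if isinstance(c, tuple):
            for p in _positions(c):
                yield (i,) + p


def _replace(tp, path, new):
    if len(path) == 1:
        return tp[: path[0]] + (new,) + tp[path[0] + 1 :]
    i = path[0]
    return tp[:i] + (_replace(tp[i], path[1:], new),) + tp[i + 1 :]


def _subtree(tp, path):
    for i in path:
        tp = tp[i]
    return tp


def rooted_topologies(labels):
    """All rooted binary labelled topologies on *labels* ((2n-3)!! of them)."""
    trees = [labels[0]]
    for leaf in labels[1:]:
        nxt = []
        for t in trees:
            nxt.append((t, leaf))  # new root above
            if isinstance(t, tuple):
                for p in _positions(t):
                    nxt.append(_replace(t, p, (_subtree(t, p), leaf)))
        trees = nxt
    return trees


def unrooted_topologies(labels):
    """All unrooted binary topologies on *labels* as tuples with a
    trifurcation at the (arbitrary) root; (2n-5)!! of them for n leaves."""
    assert len(labels) >= 3
    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        nxt = []
        for t in trees:
            for p in _positions(t):
                nxt.append(_replace(t, p, (_subtree(t, p), leaf)))
        trees = nxt
    return trees


def random_rooted_topology(labels, rng):
    """One uniformly random rooted binary labelled topology (sequential
    random edge insertion)."""
    t = labels[0]
    for leaf in labels[1:]:
        if not isinstance(t, tuple):
            t = (t, leaf)
            continue
        spots = [None] + list(_positions(t))
        p = spots[rng.integers(len(spots))]
        if p is None:
            t = (t, leaf)
        else:
            t = _replace(t, p, (_subtree(t, p), leaf))
    return t


# ---------------------------------------------------------------------------
# oracle: unrooted splits and RF
# ---------------------------------------------------------------------------


def oracle_splits(tp):
    """Non-trivial unrooted splits as frozensets of {side, complement} pairs."""
    universe = tuple_leaves(tp)
    n = len(universe)
    clades = []

    def rec(t):
        if isinstance(t, str):
            return frozenset({t})
        s = frozenset()
        for c in t:
            s |= rec(c)
        clades.append(s)
        return s

    rec(tp)
    out = set()
    for s in clades:
        if 2 <= len(s) <= n - 2:
            out.add(frozenset({s, universe - s}))
    return out


def oracle_rf(tp1, tp2):
    """Brute-force symmetric difference of enumerated split sets."""
    return len(oracle_splits(tp1) ^ oracle_splits(tp2))


# ---------------------------------------------------------------------------
# oracle: species-overlap classification
# ---------------------------------------------------------------------------


def oracle_so(tp, leaf_species):
    """Per-internal-node SO classification from first principles.

    Returns {clade leaf-label frozenset: (overlap frozenset, score, event)}
    at threshold 0.0; overlap = species occurring in >= 2 children.
    """
    out = {}

    def species_of(t):
        return {leaf_species[l] for l in tuple_leaves(t)}

    def rec(t):
        if isinstance(t, str):
            return
        child_sets = [species_of(c) for c in t]
        union = set().union(*child_sets)
        overlap = {s for s in union if sum(s in cs for cs in child_sets) >= 2}
        score = len(overlap) / len(union)
        out[tuple_leaves(t)] = (
            frozenset(overlap),
            score,
            "duplication" if overlap else "speciation",
        )
        for c in t:
            rec(c)

    rec(tp)
    return out


# ---------------------------------------------------------------------------
# oracle: LCA reconciliation (set-based)
# ---------------------------------------------------------------------------


def oracle_dl(gene_tp, species_tp, leaf_species):
    """Independent duplication/loss reconciliation.

    M(v) is found by scanning all species clades for the smallest one
    containing v's species set; losses use the depth-difference convention
    losses(v->c) = depth(M(c)) - depth(M(v)) - [v is a speciation].
    Returns (events-by-gene-clade dict, total duplications, total losses).
    """
    clades = []  # (frozenset of species, depth)

    def srec(t, depth):
        if isinstance(t, str):
            clades.append((frozenset({t}), depth))
            return frozenset({t})
        s = frozenset()
        for c in t:
            s |= srec(c, depth + 1)
        clades.append((s, depth))
        return s

    srec(species_tp, 0)

    def M(species_set):
        best = None
        for s, d in clades:
            if species_set <= s and (best is None or len(s) < len(best[0])):
                best = (s, d)
        return best  # (clade, depth)

    events = {}
    totals = {"dup": 0, "loss": 0}

    def grec(t):
        if isinstance(t, str):
            return {leaf_species[t]}
        child_sp = [grec(c) for c in t]
        sp = set().union(*child_sp)
        mv, dv = M(sp)
        child_imgs = [M(cs) for cs in child_sp]
        is_dup = any(mc == mv for mc, _ in child_imgs)
        events[tuple_leaves(t)] = "duplication" if is_dup else "speciation"
        if is_dup:
            totals["dup"] += 1
        for mc, dc in child_imgs:
            totals["loss"] += (dc - dv) - (0 if is_dup else 1)
        return sp

    grec(gene_tp)
    return events, totals["dup"], totals["loss"]


# ---------------------------------------------------------------------------
# oracle: MCC scoring
# ---------------------------------------------------------------------------


def oracle_clades(tree: PhyloTree):
    """Rooted clades (size >= 2) of a tree, by direct recursion."""
    out = []

    def rec(nd):
        if nd.is_leaf:
            return frozenset({nd.label})
        s = frozenset()
        for c in nd.children:
            s |= rec(c)
        out.append(s)
        return s

    rec(tree.root)
    return out


def oracle_mcc_index(trees):
    """Exhaustive argmax of the product of clade frequencies (earliest tie)."""
    import math

    counts = {}
    for t in trees:
        for c in oracle_clades(t):
            counts[c] = counts.get(c, 0) + 1
    n = len(trees)
    best_i, best = 0, -math.inf
    for i, t in enumerate(trees):
        score = sum(math.log(counts[c] / n) for c in oracle_clades(t))
        if score > best:
            best_i, best = i, score
    return best_i, best


# ---------------------------------------------------------------------------
# forward-recursion moment oracle for the simulator
# ---------------------------------------------------------------------------


def expected_duplications(species_tree: PhyloTree, dup_rate, loss_rate=0.0, root_copies=1):
    """Expected number of duplication events under the linear birth-death
    process, by forward recursion over expected copy number:
    E[N] grows as exp((d - l) t) along a branch; expected duplications on a
    branch are the integral of d * E[N]."""
    import math

    r = dup_rate - loss_rate
    total = 0.0
    copies = {species_tree.root.id: float(root_copies)}
    for nd in species_tree.preorder():
        if nd.parent is None:
            continue
        n0 = copies[nd.parent.id]
        L = nd.length
        if abs(r) < 1e-12:
            total += dup_rate * n0 * L
            copies[nd.id] = n0
        else:
            total += dup_rate * n0 * (math.exp(r * L) - 1.0) / r
            copies[nd.id] = n0 * math.exp(r * L)
    return total
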