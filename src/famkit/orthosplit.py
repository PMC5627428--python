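"""Species-overlap duplication detection and ortholog-set splitting.

The species-overlap (SO) criterion classifies an internal node of a gene
family tree as a duplication when its child subtrees share species: a gene
lineage can only be present twice in one species if it duplicated.  The
overlap score of a node is

    |species present in >= 2 child subtrees| / |union of child species sets|

and a node is a duplication when its score exceeds a threshold (at the
default threshold 0.0 any non-empty overlap suffices).

A *paralog-generating* node is an SO duplication whose child subtrees share
at least ``min_common`` species (default 2).  Species-specific duplications
— nodes whose subtrees overlap in a single species — typically reflect
recent lineage-specific expansion and are deliberately ignored by the
default, which keeps the number of ortholog sets small without packing
paralogs from many species into one set.  Splitting the family tree at its
paralog-generating nodes dissolves each flagged node and releases each of
its child subtrees as an independent ortholog tree; the resulting forest
partitions the leaf set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .errors import LeafSetError, TreeStructureError
from .treecore import Node, PhyloTree, SpeciesMap, map_species

__all__ = [
    "NodeEvent",
    "OrthologSet",
    "so_events",
    "find_paralog_generating",
    "split_at_nodes",
    "extract_ortholog_sets",
    "graft_orthologs",
]


@dataclass(frozen=True)
class NodeEvent:
    """SO classification of one internal gene-tree node.

    ``overlap_set`` holds the species present in at least two child
    subtrees (this is also the multifurcation rule), ``overlap_score`` the
    ratio of that set to the union of the child species sets.
    """

    node_id: int
    child_species_sets: tuple[frozenset[str], ...]
    overlap_set: frozenset[str]
    overlap_score: float
    event: str  # "speciation" | "duplication"
    paralog_generating: bool = False

    @property
    def union(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.child_species_sets:
            out |= s
        return frozenset(out)


@dataclass(frozen=True)
class OrthologSet:
    """One ortholog set released by splitting, with its extracted subtree.

    ``provenance`` is the id of the dissolved paralog-generating node that
    released this subtree, or ``None`` for the residual piece of the family
    tree that was never below a flagged node.
    """

    labels: frozenset[str]
    tree: PhyloTree
    provenance: int | None

    def __post_init__(self):
        if self.labels != self.tree.leaf_set():
            raise LeafSetError("OrthologSet labels do not match its subtree's leaves")

    def __len__(self):
        return len(self.labels)


def so_events(
    tree: PhyloTree, smap: SpeciesMap, threshold: float = 0.0
) -> list[NodeEvent]:
    """Classify every internal node by species overlap.

    A node is a duplication iff its overlap score is strictly greater than
    *threshold*; at the default 0.0 this is equivalent to "child subtrees
    share at least one species".  Multifurcations count a species as
    overlapping when it occurs in at least two children.  Events are
    returned in preorder.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    leaf_species = map_species(tree, smap)
    species_below: dict[int, frozenset[str]] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            species_below[nd.id] = frozenset({leaf_species[nd.label]})
        else:
            species_below[nd.id] = frozenset().union(
                *(species_below[c.id] for c in nd.children)
            )
    events = []
    for nd in tree.preorder():
        if nd.is_leaf:
            continue
        child_sets = tuple(species_below[c.id] for c in nd.children)
        union = frozenset().union(*child_sets)
        seen: set[str] = set()
        overlap: set[str] = set()
        for s in child_sets:
            overlap |= seen & s
            seen |= s
        score = len(overlap) / len(union)
        events.append(
            NodeEvent(
                node_id=nd.id,
                child_species_sets=child_sets,
                overlap_set=frozenset(overlap),
                overlap_score=score,
                event="duplication" if score > threshold else "speciation",
            )
        )
    return events


def find_paralog_generating(
    tree: PhyloTree, smap: SpeciesMap, min_common: int = 2
) -> list[NodeEvent]:
    """Flag nodes whose child subtrees share at least *min_common* species.

    With ``min_common=1`` this reduces to plain SO duplication detection at
    threshold 0.0.
    """
    if min_common < 1:
        raise ValueError(f"min_common must be >= 1, got {min_common}")
    return [
        replace(ev, paralog_generating=True)
        for ev in so_events(tree, smap, threshold=0.0)
        if len(ev.overlap_set) >= min_common
    ]


def _resolve_node_ids(tree: PhyloTree, nodes: Sequence) -> set[int]:
    known = {nd.id for nd in tree.preorder()}
    ids: set[int] = set()
    for item in nodes:
        if isinstance(item, NodeEvent):
            nid = item.node_id
        elif isinstance(item, Node):
            nid = item.id
        else:
            nid = int(item)
        if nid not in known:
            raise TreeStructureError(f"node {nid} is not in the tree")
        ids.add(nid)
    return ids


def split_at_nodes(tree: PhyloTree, nodes: Sequence) -> list[OrthologSet]:
    """Dissolve each flagged node; its child subtrees become independent trees.

    *nodes* may be :class:`NodeEvent` objects, :class:`~famkit.treecore.Node`
    objects or raw node ids; flagged leaves are rejected.  Flagged nodes are
    processed root-first, nested flags are honoured inside released
    subtrees, and the returned forest always partitions the leaf set.  The
    residual tree (the part never below a flagged node) is returned first
    with ``provenance=None``; unary nodes left behind by the surgery are
    suppressed with lengths summed.
    """
    flagged = _resolve_node_ids(tree, nodes)
    for nid in flagged:
        if tree.node_by_id(nid).is_leaf:
            raise TreeStructureError(f"node {nid} is a leaf; only internal nodes can be split")
    released: list[tuple[Node, int]] = []

    def rec(nd: Node) -> Node | None:
        new = Node(nd.label, nd.length, nd.support, nd.id)
        new.annotations = dict(nd.annotations)
        if nd.is_leaf:
            return new
        kept = []
        for c in nd.children:
            r = rec(c)
            if r is not None:
                kept.append(r)
        if nd.id in flagged:
            for child in kept:
                child.parent = None
                child.length = None
                released.append((child, nd.id))
            return None
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if nd.length is not None or child.length is not None:
                child.length = (nd.length or 0.0) + (child.length or 0.0)
            return child
        for c in kept:
            new.add_child(c)
        return new

    residual = rec(tree.root)
    out: list[OrthologSet] = []
    if residual is not None:
        residual.length = None
        t = PhyloTree(residual)
        out.append(OrthologSet(labels=t.leaf_set(), tree=t, provenance=None))
    for root, prov in released:
        t = PhyloTree(root)
        out.append(OrthologSet(labels=t.leaf_set(), tree=t, provenance=prov))
    return out


def extract_ortholog_sets(
    tree: PhyloTree, smap: SpeciesMap, min_common: int = 2
) -> list[OrthologSet]:
    """Split the family tree at all its paralog-generating nodes.

    Equivalent to ``split_at_nodes(tree, find_paralog_generating(tree, smap,
    min_common))``.  A single pass suffices: SO events of a node depend only
    on its descendants, so dissolving an ancestor never creates or removes a
    flag inside a released subtree (re-scanning released subtrees finds the
    identical flag set).
    """
    return split_at_nodes(tree, find_paralog_generating(tree, smap, min_common))


def graft_orthologs(
    parent_backbone: PhyloTree,
    subtrees: Sequence[PhyloTree | OrthologSet],
    attachment: Sequence[int] | None = None,
) -> PhyloTree:
    """Reattach (re-estimated) ortholog trees at their original split nodes.

    *parent_backbone* is the original family tree.  Each subtree replaces
    the child of its attachment node whose leaf set matches the subtree's
    leaf set exactly (the attachment branch length is retained from the
    backbone).  *attachment* gives the split-node id for each subtree; it
    may be omitted when :class:`OrthologSet` objects carry their provenance.
    Splitting and grafting back unchanged subtrees reproduces the original
    tree.
    """
    pairs: list[tuple[PhyloTree, int]] = []
    for i, item in enumerate(subtrees):
        if isinstance(item, OrthologSet):
            sub, prov = item.tree, item.provenance
        else:
            sub, prov = item, None
        if attachment is not None:
            prov = attachment[i]
        if prov is None:
            raise ValueError(
                f"subtree {i} has no attachment id (residual pieces are part of "
                f"the backbone and must not be grafted)"
            )
        pairs.append((sub, prov))

    result = parent_backbone.copy()
    for sub, prov in pairs:
        anchor = result.node_by_id(prov)
        if anchor.is_leaf:
            raise TreeStructureError(f"attachment node {prov} is a leaf")
        target_leaves = sub.leaf_set()
        match = None
        for c in anchor.children:
            clade = frozenset(l.label for l in _subtree_leaves(c))
            if clade == target_leaves:
                match = c
                break
        if match is None:
            raise LeafSetError(
                f"no child of node {prov} spans the grafted subtree's leaf set "
                f"({len(target_leaves)} leaves)"
            )
        new_child = sub.copy().root
        new_child.length = match.length
        new_child.parent = anchor
        anchor.children[anchor.children.index(match)] = new_child
    # grafted subtrees may reuse ids already present in the backbone: renumber
    rebuilt = result.root
    for nd in _preorder(rebuilt):
        nd.id = -1
    return PhyloTree(rebuilt)


def _subtree_leaves(nd: Node):
    stack = [nd]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _preorder(nd: Node):
    stack = [nd]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)
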