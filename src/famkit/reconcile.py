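"""LCA-mapping reconciliation: duplication/loss inference against a species tree.

Each gene-tree node v is mapped to M(v), the species-tree LCA of the
species of its descendant genes.  v is a duplication iff M(v) equals the
image of one of its children, otherwise a speciation.  Losses are implied
wherever a gene lineage passes a species-tree node without leaving
descendants in one of its daughter lineages: for a gene edge v -> c, walk
the species path from M(v) down to M(c); at every path node where the
lineage is resolved (all path nodes for a duplication v, all but M(v)
itself for a speciation) each off-path daughter branch receives one loss.
For a fully bifurcating species tree this reproduces the classic count
  losses(v -> c) = depth(M(c)) - depth(M(v)) - [v is a speciation];
at a multifurcating species node every off-path daughter is counted, the
natural generalization.

Duplications are attributed to the species branch above M(v); losses to the
branch where the lineage disappears.  Species present in the species tree
but absent from the gene family are tallied separately as "leaf absences"
(absence of the whole species from the family is not a path-implied loss
and the two kinds are not mixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ReconcileError
from .treecore import Node, PhyloTree, SpeciesMap, map_species

__all__ = ["LcaMap", "EventTable", "lca_map", "dl_events", "events_by_branch"]


@dataclass
class LcaMap:
    """Gene-node -> species-node mapping (by node, with id-keyed access)."""

    gene_tree: PhyloTree
    species_tree: PhyloTree
    mapping: dict[int, Node]  # gene node id -> species Node

    def __getitem__(self, gene_node) -> Node:
        nid = gene_node.id if isinstance(gene_node, Node) else int(gene_node)
        return self.mapping[nid]


@dataclass
class EventTable:
    """Inferred duplication/loss events, per gene node and per species branch.

    Branches are keyed by the id of the species node *below* the branch.
    """

    node_events: dict[int, str]  # gene internal node id -> "speciation"|"duplication"
    duplications_by_branch: dict[int, int]
    losses_by_branch: dict[int, int]
    absent_species: list[str] = field(default_factory=list)

    @property
    def total_duplications(self) -> int:
        return sum(self.duplications_by_branch.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses_by_branch.values())

    def duplication_node_ids(self) -> set[int]:
        return {nid for nid, ev in self.node_events.items() if ev == "duplication"}


def _species_index(species_tree: PhyloTree):
    by_label: dict[str, Node] = {}
    depth: dict[int, int] = {}
    for nd in species_tree.preorder():
        depth[nd.id] = 0 if nd.parent is None else depth[nd.parent.id] + 1
        if nd.is_leaf:
            by_label[nd.label] = nd
    return by_label, depth


def _lca(a: Node, b: Node, depth: dict[int, int]) -> Node:
    while a is not b:
        if depth[a.id] >= depth[b.id]:
            a = a.parent
        else:
            b = b.parent
    return a


def lca_map(
    gene_tree: PhyloTree, species_tree: PhyloTree, smap: SpeciesMap
) -> LcaMap:
    """Standard LCA mapping, computed bottom-up over the gene tree.

    Every species of a gene leaf must occur in the species tree.
    Multifurcating gene nodes map to the LCA over all children's images.
    """
    leaf_species = map_species(gene_tree, smap)
    by_label, depth = _species_index(species_tree)
    unknown = sorted(set(leaf_species.values()) - set(by_label))
    if unknown:
        raise ReconcileError(f"species not in species tree: {unknown}")
    mapping: dict[int, Node] = {}
    for nd in gene_tree.postorder():
        if nd.is_leaf:
            mapping[nd.id] = by_label[leaf_species[nd.label]]
        else:
            img = mapping[nd.children[0].id]
            for c in nd.children[1:]:
                img = _lca(img, mapping[c.id], depth)
            mapping[nd.id] = img
    return LcaMap(gene_tree=gene_tree, species_tree=species_tree, mapping=mapping)


def dl_events(
    gene_tree: PhyloTree, species_tree: PhyloTree, smap: SpeciesMap
) -> EventTable:
    """Infer duplications and losses from the LCA mapping (see module docs)."""
    lmap = lca_map(gene_tree, species_tree, smap)
    _, depth = _species_index(species_tree)
    dup_by_branch: dict[int, int] = {nd.id: 0 for nd in species_tree.preorder()}
    loss_by_branch: dict[int, int] = {nd.id: 0 for nd in species_tree.preorder()}
    node_events: dict[int, str] = {}

    for v in gene_tree.preorder():
        if v.is_leaf:
            continue
        mv = lmap[v]
        is_dup = any(lmap[c] is mv for c in v.children)
        node_events[v.id] = "duplication" if is_dup else "speciation"
        if is_dup:
            dup_by_branch[mv.id] += 1
        for c in v.children:
            mc = lmap[c]
            # species path M(v) -> M(c), top down
            path = []
            s = mc
            while s is not mv:
                path.append(s)
                s = s.parent
            path.append(mv)
            path.reverse()  # [mv, ..., mc]
            # loss sites: path nodes where the lineage is committed to one
            # daughter; skip M(v) itself when v is a speciation (the lineage
            # only enters a single daughter of M(v) there), and never mc.
            start = 0 if is_dup else 1
            for i in range(start, len(path) - 1):
                s, nxt = path[i], path[i + 1]
                for d in s.children:
                    if d is not nxt:
                        loss_by_branch[d.id] += 1

    present = set(map_species(gene_tree, smap).values())
    absent = sorted(sp for sp in species_tree.leaf_set() if sp not in present)
    return EventTable(
        node_events=node_events,
        duplications_by_branch=dup_by_branch,
        losses_by_branch=loss_by_branch,
        absent_species=absent,
    )


def events_by_branch(table: EventTable, species_tree: PhyloTree) -> pd.DataFrame:
    """Per-species-branch event summary, one row per branch, TSV-ready.

    A branch is named by the label of the node below it, or by the sorted
    species clade it subtends when unlabelled; totals over rows equal the
    table's totals.
    """
    clades: dict[int, list[str]] = {}
    for nd in species_tree.postorder():
        if nd.is_leaf:
            clades[nd.id] = [nd.label]
        else:
            clades[nd.id] = sorted(l for c in nd.children for l in clades[c.id])
    rows = []
    for nd in species_tree.preorder():
        name = nd.label if nd.label else "|".join(clades[nd.id])
        rows.append(
            {
                "branch": name,
                "node_id": nd.id,
                "is_root": nd.parent is None,
                "n_species": len(clades[nd.id]),
                "duplication_count": table.duplications_by_branch.get(nd.id, 0),
                "loss_count": table.losses_by_branch.get(nd.id, 0),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["branch", "node_id", "is_root", "n_species", "duplication_count", "loss_count"],
    )
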