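"""Robinson-Foulds machinery and the duplication-aware family nRF distance.

The headline statistic compares a gene *family* tree — which contains
paralogs and therefore cannot be compared to the species tree directly —
with the species tree, via a decomposition pipeline:

1. split the family tree into ortholog trees at its paralog-generating
   nodes (:func:`famkit.orthosplit.extract_ortholog_sets`);
2. split each ortholog tree at every remaining species-overlap duplication
   into single-copy subtrees, relabelling leaves to species names
   (:func:`treeko_decompose`);
3. compute the normalized Robinson-Foulds distance of every decomposed
   subtree against the species tree restricted to their common species;
4. average per ortholog tree, then average the per-ortholog means.

nRF = RF / (|B1| + |B2|), where B1, B2 are the non-trivial bipartition sets
of the two trees under the unrooted interpretation; for two binary trees on
n shared leaves the denominator is 2(n-3).  Subtrees sharing fewer than 4
leaves with the species tree carry no topological signal and are skipped
(and counted as such).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import LeafSetError, SpeciesMapError, TreeStructureError
from .orthosplit import OrthologSet, extract_ortholog_sets, so_events, split_at_nodes
from .treecore import PhyloTree, SpeciesMap, map_species, prune_to_leafset

__all__ = [
    "BipartitionSet",
    "DistanceReport",
    "OrthologReport",
    "FamilyDistanceReport",
    "bipartitions",
    "rf_distance",
    "treeko_decompose",
    "family_nrf",
]


@dataclass(frozen=True)
class BipartitionSet:
    """Non-trivial bipartitions of an unrooted tree.

    Each split is stored as its canonical side: the lexicographically
    smaller of the two leaf-label tuples.
    """

    universe: frozenset[str]
    splits: frozenset[frozenset[str]]

    def __len__(self):
        return len(self.splits)


def _canonical_side(side: frozenset[str], universe: frozenset[str]) -> frozenset[str]:
    other = universe - side
    return side if tuple(sorted(side)) <= tuple(sorted(other)) else other


def bipartitions(tree: PhyloTree) -> BipartitionSet:
    """Bipartitions induced by internal edges under the unrooted reading.

    The artificial split at the root (both root-child edges of a bifurcating
    root induce the same bipartition) is merged; splits with a side smaller
    than 2 are trivial and excluded.  A star tree yields the empty set.
    """
    universe = tree.leaf_set()
    below: dict[int, frozenset[str]] = {}
    splits: set[frozenset[str]] = set()
    for nd in tree.postorder():
        if nd.is_leaf:
            below[nd.id] = frozenset({nd.label})
            continue
        clade = frozenset().union(*(below[c.id] for c in nd.children))
        below[nd.id] = clade
        if nd.parent is None:
            continue
        if len(clade) < 2 or len(universe - clade) < 2:
            continue
        splits.add(_canonical_side(clade, universe))
    return BipartitionSet(universe=universe, splits=frozenset(splits))


@dataclass(frozen=True)
class DistanceReport:
    """RF distance between two trees restricted to their common leaves."""

    rf: int
    max_rf: int
    nrf: float
    n_common_leaves: int
    skipped: bool = False
    reason: str | None = None


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> DistanceReport:
    """Robinson-Foulds distance on the shared leaf set.

    Both trees are pruned to their common leaves and read as unrooted;
    rf = |B1 symmetric-difference B2| and max_rf = |B1| + |B2|.  When fewer
    than 4 leaves are shared the comparison is degenerate and the report is
    flagged ``skipped``.  No common leaf at all is an error.
    """
    common = t1.leaf_set() & t2.leaf_set()
    if not common:
        raise LeafSetError("trees share no leaf labels")
    if len(common) < 4:
        return DistanceReport(
            rf=0,
            max_rf=0,
            nrf=0.0,
            n_common_leaves=len(common),
            skipped=True,
            reason=f"only {len(common)} common leaves (need 4)",
        )
    b1 = bipartitions(prune_to_leafset(t1, common))
    b2 = bipartitions(prune_to_leafset(t2, common))
    rf = len(b1.splits ^ b2.splits)
    max_rf = len(b1) + len(b2)
    nrf = rf / max_rf if max_rf > 0 else 0.0
    return DistanceReport(rf=rf, max_rf=max_rf, nrf=nrf, n_common_leaves=len(common))


def treeko_decompose(
    ortholog_tree: PhyloTree, smap: SpeciesMap, so_threshold: float = 0.0
) -> list[PhyloTree]:
    """Split a gene tree at every SO duplication into single-copy subtrees.

    Every node whose overlap score exceeds *so_threshold* is dissolved
    (recursively; the released forest partitions the leaf set) and the
    leaves of each returned subtree are relabelled to species names.  In a
    duplication-free subtree the child species sets of every node are
    disjoint, so each subtree holds at most one gene per species — this is
    asserted, a violation being an internal error.
    """
    events = so_events(ortholog_tree, smap, threshold=so_threshold)
    leaf_species = map_species(ortholog_tree, smap)
    dup_ids = [ev.node_id for ev in events if ev.event == "duplication"]
    pieces = split_at_nodes(ortholog_tree, dup_ids)
    out: list[PhyloTree] = []
    for piece in pieces:
        t = piece.tree
        seen: set[str] = set()
        for leaf in t.leaves():
            sp = leaf_species[leaf.label]
            if sp in seen:
                raise TreeStructureError(
                    f"duplicate species {sp!r} in a decomposed subtree: "
                    f"SO splitting is inconsistent"
                )
            seen.add(sp)
            leaf.label = sp
        out.append(PhyloTree(t.root))
    return out


@dataclass
class OrthologReport:
    """Per-ortholog-tree breakdown of the decomposed-subtree distances."""

    provenance: int | None
    n_members: int
    subtree_reports: list[DistanceReport]
    mean_nrf: float | None  # None when every subtree was skipped

    @property
    def n_subtrees(self) -> int:
        return len(self.subtree_reports)

    @property
    def n_skipped(self) -> int:
        return sum(1 for r in self.subtree_reports if r.skipped)


@dataclass
class FamilyDistanceReport:
    """Duplication-aware average nRF between a family tree and the species tree.

    ``overall_mean_nrf`` is the unweighted mean of the per-ortholog-tree
    means (each ortholog tree counts once, however many single-copy
    subtrees it decomposed into); ``pooled_mean_nrf`` pools all non-skipped
    subtrees instead and is reported as a secondary figure.
    """

    ortholog_reports: list[OrthologReport] = field(default_factory=list)
    overall_mean_nrf: float | None = None
    pooled_mean_nrf: float | None = None
    all_skipped: bool = False

    @property
    def n_ortholog_sets(self) -> int:
        return len(self.ortholog_reports)

    @property
    def n_subtrees(self) -> int:
        return sum(r.n_subtrees for r in self.ortholog_reports)

    @property
    def n_skipped(self) -> int:
        return sum(r.n_skipped for r in self.ortholog_reports)

    def to_dict(self) -> dict:
        return {
            "overall_mean_nrf": self.overall_mean_nrf,
            "pooled_mean_nrf": self.pooled_mean_nrf,
            "n_ortholog_sets": self.n_ortholog_sets,
            "n_subtrees": self.n_subtrees,
            "n_skipped_subtrees": self.n_skipped,
            "all_skipped": self.all_skipped,
            "ortholog_trees": [
                {
                    "provenance": r.provenance,
                    "n_members": r.n_members,
                    "n_subtrees": r.n_subtrees,
                    "n_skipped": r.n_skipped,
                    "mean_nrf": r.mean_nrf,
                }
                for r in self.ortholog_reports
            ],
        }

    def to_frame(self) -> pd.DataFrame:
        """One row per decomposed subtree, TSV-ready."""
        rows = []
        for oi, rep in enumerate(self.ortholog_reports):
            for si, r in enumerate(rep.subtree_reports):
                rows.append(
                    {
                        "ortholog_tree": oi,
                        "provenance": rep.provenance,
                        "subtree": si,
                        "n_common_leaves": r.n_common_leaves,
                        "rf": r.rf,
                        "max_rf": r.max_rf,
                        "nrf": r.nrf,
                        "skipped": r.skipped,
                        "reason": r.reason or "",
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "ortholog_tree",
                "provenance",
                "subtree",
                "n_common_leaves",
                "rf",
                "max_rf",
                "nrf",
                "skipped",
                "reason",
            ],
        )


def family_nrf(
    family_tree: PhyloTree,
    species_tree: PhyloTree,
    smap: SpeciesMap,
    min_common: int = 2,
    so_threshold: float = 0.0,
) -> FamilyDistanceReport:
    """Average normalized RF distance of a gene family tree from the species tree.

    Pipeline: extract ortholog sets at paralog-generating nodes
    (*min_common* shared species), decompose each ortholog tree at its SO
    duplications (*so_threshold*), compare every decomposed single-copy
    subtree against the species tree restricted to their common species,
    average per ortholog tree over non-skipped subtrees, then take the
    unweighted mean of the per-ortholog means.

    Every species occurring in the family must be present in the species
    tree; unknown species are reported by name.
    """
    leaf_species = map_species(family_tree, smap)
    unknown = sorted(set(leaf_species.values()) - species_tree.leaf_set())
    if unknown:
        raise SpeciesMapError(f"species not in species tree: {unknown}")

    report = FamilyDistanceReport()
    for oset in extract_ortholog_sets(family_tree, smap, min_common=min_common):
        sub_reports = []
        for subtree in treeko_decompose(oset.tree, smap, so_threshold=so_threshold):
            sub_reports.append(rf_distance(subtree, species_tree))
        usable = [r.nrf for r in sub_reports if not r.skipped]
        report.ortholog_reports.append(
            OrthologReport(
                provenance=oset.provenance,
                n_members=len(oset),
                subtree_reports=sub_reports,
                mean_nrf=sum(usable) / len(usable) if usable else None,
            )
        )
    means = [r.mean_nrf for r in report.ortholog_reports if r.mean_nrf is not None]
    pooled = [
        r.nrf
        for rep in report.ortholog_reports
        for r in rep.subtree_reports
        if not r.skipped
    ]
    if means:
        report.overall_mean_nrf = sum(means) / len(means)
        report.pooled_mean_nrf = sum(pooled) / len(pooled)
    else:
        report.all_skipped = True
    return report
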