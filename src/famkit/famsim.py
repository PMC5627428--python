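"""Gene-family evolution simulator: duplication, loss and transfer along a
dated species tree, with ground-truth event logs.

The model is a linear birth-death-transfer process run independently for
every gene lineage, Gillespie-style, in species-tree time (root -> tips):
a lineage on a species branch waits Exp(lam_d + lam_l + lam_t); a
duplication splits it in place, a loss terminates it, a transfer copies it
onto a branch drawn uniformly among the species branches co-existing at
that moment (the donor excluded).  At every species-tree node each
surviving lineage bifurcates into both daughter branches.  Rates are per
lineage per unit branch time.

The full gene tree (extinct lineages included) is kept alongside the
observable tree (extinct lineages pruned, unary nodes suppressed with
lengths summed); node ids are preserved by the pruning, so an observable
internal node can be traced back to the logged event that created it.
Extant leaves are labelled ``g<k>_<species>``.

Everything is reproducible from the seed.  This generator emulates the
gene-family histories the pipeline's detectors are built for; it does not
emulate sequence evolution, rate heterogeneity or incomplete lineage
sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SimulationError
from .treecore import Node, PhyloTree, SpeciesMap, prune_to_leafset

__all__ = [
    "SimParams",
    "SimEvent",
    "SimResult",
    "simulate_family",
    "simulate_replicates",
    "prune_extinct",
    "example_species_tree",
]

_ULTRAMETRIC_ATOL = 1e-6

#: Balanced, ultrametric 8-species tree of height 1.0 used as the default
#: simulation fixture (times chosen to spread splits over the tree depth).
_EXAMPLE_8_SPECIES = (
    "((((A:0.15,B:0.15):0.2,(C:0.2,D:0.2):0.15):0.3,(E:0.25,F:0.25):0.4):0.35,"
    "(G:0.55,H:0.55):0.45);"
)


def example_species_tree() -> PhyloTree:
    """The package's stock dated 8-species tree (ultrametric, height 1)."""
    from .treecore import parse_newick

    return parse_newick(_EXAMPLE_8_SPECIES)


@dataclass(frozen=True)
class SimParams:
    """Per-lineage event rates (events / lineage / unit branch time)."""

    dup_rate: float = 0.0
    loss_rate: float = 0.0
    transfer_rate: float = 0.0
    root_copies: int = 1

    def __post_init__(self):
        if min(self.dup_rate, self.loss_rate, self.transfer_rate) < 0:
            raise SimulationError("rates must be non-negative")
        if self.root_copies < 1:
            raise SimulationError("root_copies must be >= 1")


@dataclass(frozen=True)
class SimEvent:
    """One logged event.  ``species_branch`` is the id of the species node
    below the branch the lineage sat on; ``gene_node_id`` the id of the gene
    node the event created (a loss leaf for losses)."""

    kind: str  # "duplication" | "loss" | "transfer"
    time: float
    species_branch: int
    gene_node_id: int
    recipient_branch: int | None = None


@dataclass
class SimResult:
    """Simulated family: full tree, observable tree and ground-truth log."""

    full_tree: PhyloTree
    observable: PhyloTree | None
    events: list[SimEvent]
    extinct: bool
    params: SimParams
    species_tree: PhyloTree
    node_species: dict[int, int] = field(default_factory=dict)  # gene node -> species node

    @property
    def n_extant(self) -> int:
        return 0 if self.observable is None else self.observable.n_leaves()

    def species_map(self) -> SpeciesMap:
        """Map matching the simulator's ``g<k>_<species>`` leaf labels."""
        return SpeciesMap.from_delimiter("_", field=0, from_end=True)

    def events_of_kind(self, kind: str) -> list[SimEvent]:
        return [e for e in self.events if e.kind == kind]


def _species_times(species_tree: PhyloTree) -> dict[int, float]:
    times: dict[int, float] = {}
    for nd in species_tree.preorder():
        if nd.parent is None:
            times[nd.id] = 0.0
            continue
        if nd.length is None:
            raise SimulationError(f"species branch above node {nd.id} has no length")
        if nd.length <= 0:
            raise SimulationError(f"species branch above node {nd.id} has zero length")
        times[nd.id] = times[nd.parent.id] + nd.length
    return times


def _check_ultrametric(species_tree: PhyloTree, times: dict[int, float]) -> bool:
    tip_times = [times[l.id] for l in species_tree.leaves()]
    height = max(tip_times)
    tol = _ULTRAMETRIC_ATOL * max(height, 1.0)
    return max(tip_times) - min(tip_times) <= tol


def simulate_family(
    species_tree: PhyloTree, params: SimParams, seed: int | np.random.Generator
) -> SimResult:
    """Simulate one gene family along *species_tree* (see module docs).

    Root copies start at the species root's own time (origin = root, no stem
    branch).  A transfer drawn at a moment when no other species branch
    co-exists (possible only on degenerate trees) is discarded.  Raises
    :class:`SimulationError` on non-positive branch lengths, or on a
    non-ultrametric tree when the transfer rate is positive.
    """
    if species_tree.n_leaves() < 2:
        raise SimulationError("species tree needs at least 2 species")
    times = _species_times(species_tree)
    if params.transfer_rate > 0 and not _check_ultrametric(species_tree, times):
        raise SimulationError("transfer_rate > 0 requires an ultrametric species tree")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    sp_nodes = {nd.id: nd for nd in species_tree.preorder()}
    branches = [
        (nd.id, times[nd.parent.id], times[nd.id])
        for nd in species_tree.preorder()
        if nd.parent is not None
    ]
    total_rate = params.dup_rate + params.loss_rate + params.transfer_rate
    events: list[SimEvent] = []
    gene_times: dict[int, float] = {}
    node_species: dict[int, int] = {}
    counter = [0]

    def new_node(event: str, sp_id: int, t: float) -> Node:
        nd = Node(id=counter[0])
        counter[0] += 1
        nd.annotations["event"] = event
        node_species[nd.id] = sp_id
        gene_times[nd.id] = t
        return nd

    def speciate(sp: Node, t: float) -> Node:
        """A lineage sitting exactly on species node *sp* at time *t*."""
        if sp.is_leaf:
            leaf = new_node("extant", sp.id, t)
            leaf.label = f"@extant@{sp.label}@{leaf.id}"
            return leaf
        nd = new_node("speciation", sp.id, t)
        for child in sp.children:
            nd.add_child(evolve(child, t))
        return nd

    def evolve(sp: Node, t: float) -> Node:
        """A lineage entering the branch above species node *sp* at time *t*."""
        t_end = times[sp.id]
        while True:
            wait = rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
            if t + wait >= t_end:
                return speciate(sp, t_end)
            t += wait
            u = rng.random() * total_rate
            if u < params.dup_rate:
                nd = new_node("duplication", sp.id, t)
                nd.add_child(evolve(sp, t))
                nd.add_child(evolve(sp, t))
                events.append(SimEvent("duplication", t, sp.id, nd.id))
                return nd
            if u < params.dup_rate + params.loss_rate:
                nd = new_node("loss", sp.id, t)
                nd.label = f"@loss@{nd.id}"
                events.append(SimEvent("loss", t, sp.id, nd.id))
                return nd
            # transfer: uniform over co-existing branches, donor excluded
            candidates = [b for b, t0, t1 in branches if b != sp.id and t0 < t < t1]
            if not candidates:
                continue
            recipient = candidates[rng.integers(len(candidates))]
            nd = new_node("transfer", sp.id, t)
            nd.add_child(evolve(sp, t))
            nd.add_child(evolve(sp_nodes[recipient], t))
            events.append(SimEvent("transfer", t, sp.id, nd.id, recipient))
            return nd

    sroot = species_tree.root
    if params.root_copies == 1:
        root = speciate(sroot, 0.0)
    else:
        root = new_node("origin", sroot.id, 0.0)
        for _ in range(params.root_copies):
            root.add_child(speciate(sroot, 0.0))

    # branch lengths from absolute times; label extant leaves g<k>_<species>
    k = 0
    stack = [root]
    order = []
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(reversed(nd.children))
    for nd in order:
        if nd.parent is not None:
            nd.length = gene_times[nd.id] - gene_times[nd.parent.id]
        if nd.is_leaf and nd.annotations.get("event") == "extant":
            k += 1
            sp_label = sp_nodes[node_species[nd.id]].label
            nd.label = f"g{k}_{sp_label}"

    full = PhyloTree(root)
    result = SimResult(
        full_tree=full,
        observable=None,
        events=events,
        extinct=False,
        params=params,
        species_tree=species_tree,
        node_species=node_species,
    )
    result.observable = prune_extinct(result)
    result.extinct = result.observable is None
    return result


def prune_extinct(result: SimResult) -> PhyloTree | None:
    """Observable tree: extinct lineages removed, unary nodes suppressed with
    branch lengths summed.  Returns ``None`` when the family went extinct
    (``result.extinct`` is the flag).  Node ids are preserved, so surviving
    internal nodes can be traced to their event in the full tree."""
    extant = [
        l.label
        for l in result.full_tree.leaves()
        if l.annotations.get("event") == "extant"
    ]
    if not extant:
        return None
    return prune_to_leafset(result.full_tree, extant)


def simulate_replicates(
    species_tree: PhyloTree, params: SimParams, n_replicates: int, seed: int
) -> list[SimResult]:
    """Independent replicate families, reproducible from (*seed*, index)."""
    return [
        simulate_family(species_tree, params, np.random.default_rng([seed, i]))
        for i in range(n_replicates)
    ]
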