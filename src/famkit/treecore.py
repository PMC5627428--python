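"""Rooted phylogenetic trees: data model, newick/NEXUS I/O, species mapping.

The :class:`PhyloTree` is the package's universal currency: a rooted tree
whose nodes carry an optional label, branch length, support value and a free
string annotation map.  Parsing is delegated to :mod:`dendropy` (quoted
labels, ``[...]`` comments, BEAST-dialect NEXUS with Translate blocks) and the
result is converted into this lightweight structure, which the algorithmic
modules (species overlap, tree distances, reconciliation, simulation)
manipulate directly.

Conventions
-----------
* All trees are read as rooted; unrooted interpretation happens only inside
  Robinson-Foulds computations.
* Underscores in labels are kept literal (no blank substitution).
* ``[...]`` comments are dropped on read.
* A numeric internal-node label is interpreted as a support value when no
  explicit support is present (BEAST/ALE output convention).
* Unary internal nodes are suppressed on read, branch lengths summed.
* An absent branch length means "no length information", never 0.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field as _dc_field
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import dendropy

from .errors import (
    LeafSetError,
    NewickParseError,
    SampleError,
    SpeciesMapError,
    TreeStructureError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "SpeciesMap",
    "TreeSample",
    "parse_newick",
    "write_newick",
    "read_tree_sample",
    "map_species",
    "prune_to_leafset",
]

# characters safe in an unquoted newick label
_UNQUOTED_OK = re.compile(r"^[A-Za-z0-9_.\-|/+#*&@]+$")


class Node:
    """A node of a rooted tree.

    Attributes
    ----------
    parent : Node or None
        ``None`` exactly at the root.
    children : list of Node
        Ordered; empty at leaves.
    label : str or None
        Required and unique for leaves, optional for internal nodes.
    length : float or None
        Branch length of the edge above this node; ``None`` = no information.
    support : float or None
        Support/posterior attached to the clade below this node.
    annotations : dict[str, str]
        Free-form string annotations.
    id : int
        Tree-unique identifier, stable under :meth:`PhyloTree.copy`.
    """

    __slots__ = ("parent", "children", "label", "length", "support", "annotations", "id")

    def __init__(self, label=None, length=None, support=None, id=-1):
        self.parent: "Node | None" = None
        self.children: list["Node"] = []
        self.label: str | None = label
        self.length: float | None = length
        self.support: float | None = support
        self.annotations: dict[str, str] = {}
        self.id: int = id

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node id={self.id} {kind} label={self.label!r}>"


class PhyloTree:
    """A rooted phylogenetic tree with uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        self._renumber()
        self.validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    # -- traversal ----------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [nd for nd in self.preorder() if not nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels())

    def node_by_id(self, node_id: int) -> Node:
        for nd in self.preorder():
            if nd.id == node_id:
                return nd
        raise TreeStructureError(f"no node with id {node_id} in tree")

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def total_length(self) -> float:
        """Sum of all defined branch lengths."""
        return sum(nd.length for nd in self.preorder() if nd.length is not None)

    # -- maintenance --------------------------------------------------------

    def _renumber(self) -> None:
        """Assign fresh preorder ids to any node still carrying id -1."""
        used = {nd.id for nd in self.preorder() if nd.id >= 0}
        nxt = max(used, default=-1) + 1
        for nd in self.preorder():
            if nd.id < 0:
                nd.id = nxt
                nxt += 1

    def validate(self) -> None:
        seen_ids: set[int] = set()
        labels: set[str] = set()
        for nd in self.preorder():
            if nd.id in seen_ids:
                raise TreeStructureError(f"duplicate node id {nd.id}")
            seen_ids.add(nd.id)
            for c in nd.children:
                if c.parent is not nd:
                    raise TreeStructureError("child/parent pointer mismatch")
            if nd.is_leaf:
                if not nd.label:
                    raise TreeStructureError("leaf without label")
                if nd.label in labels:
                    raise TreeStructureError(f"duplicate leaf label {nd.label!r}")
                labels.add(nd.label)
            elif len(nd.children) == 1 and nd is not self.root:
                raise TreeStructureError("unary internal node survived normalization")
            if nd.length is not None and nd.length < 0:
                raise TreeStructureError(f"negative branch length {nd.length}")
        if self.root.parent is not None:
            raise TreeStructureError("root has a parent")

    def copy(self) -> "PhyloTree":
        """Deep copy; node ids are preserved."""

        def rec(nd: Node) -> Node:
            new = Node(nd.label, nd.length, nd.support, nd.id)
            new.annotations = dict(nd.annotations)
            for c in nd.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root))

    # -- serialization ------------------------------------------------------

    def to_newick(self, precision: int = 6, annotations: bool = False) -> str:
        return write_newick(self, precision=precision, annotations=annotations)

    def __str__(self):
        return self.to_newick()

    def isomorphic(self, other: "PhyloTree") -> bool:
        """Topology + leaf-label equality as rooted trees (lengths ignored)."""
        return _canonical(self.root) == _canonical(other.root)


def _canonical(nd: Node):
    if nd.is_leaf:
        return nd.label
    return tuple(sorted((_canonical(c) for c in nd.children), key=repr))


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False


def _from_dendropy_node(dnode) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
    else:
        label, support = dnode.label, None
        if label is not None and _looks_numeric(label):
            support, label = float(label), None
        node = Node(label=label, length=dnode.edge.length, support=support)
        for c in dnode.child_nodes():
            node.add_child(_from_dendropy_node(c))
    return node


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    root = _from_dendropy_node(dtree.seed_node)
    root = _suppress_unary(root)
    if root.is_leaf and not root.label:
        raise NewickParseError("empty tree")
    return PhyloTree(root)


def _suppress_unary(root: Node) -> Node:
    """Remove unary internal nodes, summing branch lengths along the spliced path."""
    # root chain first
    while len(root.children) == 1:
        child = root.children[0]
        child.parent = None
        child.length = None  # a root has no incoming edge
        root = child
    stack = [root]
    while stack:
        nd = stack.pop()
        new_children = []
        for c in nd.children:
            while len(c.children) == 1:
                only = c.children[0]
                if c.length is not None or only.length is not None:
                    only.length = (c.length or 0.0) + (only.length or 0.0)
                c = only
            c.parent = nd
            new_children.append(c)
            stack.append(c)
        nd.children = new_children
    return root


def parse_newick(text: str) -> PhyloTree:
    """Parse a single newick tree.

    Quoted labels and ``[...]`` comments are handled (comments dropped);
    underscores are literal.  Raises :class:`NewickParseError` naming the
    offending position for malformed input, and on duplicate leaf labels.
    """
    if not text or not text.strip():
        raise NewickParseError("empty input")
    if not text.strip().endswith(";"):
        raise NewickParseError("newick string must be terminated by ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "parenthes" in msg.lower() or "end of stream" in msg.lower():
            msg = f"unbalanced parentheses: {msg}"
        raise NewickParseError(msg) from exc
    try:
        return _from_dendropy(dtree)
    except TreeStructureError as exc:
        raise NewickParseError(str(exc)) from exc


def _format_length(x: float, precision: int) -> str:
    s = f"{x:.{precision}f}"
    if "." in s:
        s = s.rstrip("0").rstrip(".")
    return s or "0"


def _format_label(label: str) -> str:
    if _UNQUOTED_OK.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _node_newick(nd: Node, precision: int, annotations: bool) -> str:
    if nd.is_leaf:
        s = _format_label(nd.label)
    else:
        inner = ",".join(_node_newick(c, precision, annotations) for c in nd.children)
        tag = ""
        if nd.label is not None:
            tag = _format_label(nd.label)
        elif nd.support is not None:
            tag = _format_length(nd.support, precision)
        s = f"({inner}){tag}"
    if annotations and nd.annotations:
        body = ",".join(f"{k}={v}" for k, v in sorted(nd.annotations.items()))
        s += f"[&{body}]"
    if nd.length is not None:
        s += ":" + _format_length(nd.length, precision)
    return s


def write_newick(tree: PhyloTree, precision: int = 6, annotations: bool = False) -> str:
    """Serialize to newick; round-trips with :func:`parse_newick` up to
    branch-length precision.  With ``annotations=True`` node annotation maps
    are emitted as ``[&key=value,...]`` comments (informational; dropped on
    re-parse)."""
    return _node_newick(tree.root, precision, annotations) + ";"


# ---------------------------------------------------------------------------
# species mapping
# ---------------------------------------------------------------------------


@dataclass
class SpeciesMap:
    """Rule mapping gene leaf labels to species identifiers.

    Exactly one of three modes:

    ``table``
        explicit gene-label -> species-label dictionary;
    ``delimiter``
        split the label on a character and take a field (``from_end`` counts
        fields from the right, so field 0 with ``from_end=True`` is the last);
    ``regex``
        a pattern with exactly one capture group.

    ``on_unmapped`` decides what happens for a leaf the rule cannot map:
    ``"error"`` raises :class:`SpeciesMapError`, ``"drop"`` prunes the leaf.
    """

    mode: str
    table: Mapping[str, str] | None = None
    delimiter: str = "_"
    field: int = 0
    from_end: bool = True
    pattern: str | None = None
    on_unmapped: str = "error"
    _compiled: "re.Pattern | None" = _dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.mode not in {"table", "delimiter", "regex"}:
            raise SpeciesMapError(f"unknown SpeciesMap mode {self.mode!r}")
        if self.on_unmapped not in {"error", "drop"}:
            raise SpeciesMapError(f"unknown on_unmapped policy {self.on_unmapped!r}")
        if self.mode == "regex":
            if self.pattern is None:
                raise SpeciesMapError("regex mode requires a pattern")
            self._compiled = re.compile(self.pattern)
            if self._compiled.groups != 1:
                raise SpeciesMapError(
                    f"regex pattern must have exactly one capture group, "
                    f"got {self._compiled.groups}"
                )
        if self.mode == "table" and self.table is None:
            raise SpeciesMapError("table mode requires a table")

    # constructors ----------------------------------------------------------

    @classmethod
    def from_table(cls, table: Mapping[str, str], on_unmapped: str = "error") -> "SpeciesMap":
        return cls(mode="table", table=dict(table), on_unmapped=on_unmapped)

    @classmethod
    def from_tsv(cls, path, on_unmapped: str = "error") -> "SpeciesMap":
        """Two-column TSV ``gene_label<TAB>species_label``; '#' comments allowed."""
        table: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise SpeciesMapError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                    )
                table[parts[0]] = parts[1]
        return cls.from_table(table, on_unmapped=on_unmapped)

    @classmethod
    def from_delimiter(
        cls, delimiter: str = "_", field: int = 0, from_end: bool = True, on_unmapped: str = "error"
    ) -> "SpeciesMap":
        return cls(
            mode="delimiter",
            delimiter=delimiter,
            field=field,
            from_end=from_end,
            on_unmapped=on_unmapped,
        )

    @classmethod
    def from_regex(cls, pattern: str, on_unmapped: str = "error") -> "SpeciesMap":
        return cls(mode="regex", pattern=pattern, on_unmapped=on_unmapped)

    # resolution ------------------------------------------------------------

    def resolve(self, label: str) -> str | None:
        """Species for one leaf label, or None if the rule does not apply."""
        if self.mode == "table":
            return self.table.get(label)
        if self.mode == "delimiter":
            parts = label.split(self.delimiter)
            idx = -(self.field + 1) if self.from_end else self.field
            try:
                return parts[idx] or None
            except IndexError:
                return None
        m = self._compiled.search(label)
        return m.group(1) if m else None


def map_species(tree: PhyloTree, smap: SpeciesMap) -> dict[str, str]:
    """Map every leaf of *tree* to its species.

    Returns a total leaf-label -> species-label dict over retained leaves.
    Under ``on_unmapped="drop"`` unmapped leaves are pruned from *tree*
    in place (and logged); under ``"error"`` an unmapped leaf raises
    :class:`SpeciesMapError` naming it.
    """
    mapping: dict[str, str] = {}
    unmapped: list[str] = []
    for leaf in tree.leaves():
        sp = smap.resolve(leaf.label)
        if sp is None:
            unmapped.append(leaf.label)
        else:
            mapping[leaf.label] = sp
    if unmapped:
        if smap.on_unmapped == "error":
            raise SpeciesMapError(f"leaf {unmapped[0]!r} has no species mapping")
        logger.warning("dropping %d unmapped leaves: %s", len(unmapped), ", ".join(unmapped))
        keep = tree.leaf_set() - set(unmapped)
        if not keep:
            raise SpeciesMapError("no leaf could be mapped to a species")
        pruned = prune_to_leafset(tree, keep)
        tree.root = pruned.root
    return mapping


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def prune_to_leafset(tree: PhyloTree, keep: Iterable[str]) -> PhyloTree:
    """Induced subtree on the leaf set *keep*.

    Unary nodes along retained paths are suppressed with their branch
    lengths summed, so the total retained path length is conserved.  Node
    ids are preserved from the original tree.
    """
    keep = frozenset(keep)
    leaves = tree.leaf_set()
    if not keep:
        raise LeafSetError("keep set is empty")
    extra = keep - leaves
    if extra:
        raise LeafSetError(f"labels not in tree: {sorted(extra)}")

    def rec(nd: Node) -> Node | None:
        if nd.is_leaf:
            if nd.label not in keep:
                return None
            new = Node(nd.label, nd.length, nd.support, nd.id)
            new.annotations = dict(nd.annotations)
            return new
        kept = [r for r in (rec(c) for c in nd.children) if r is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            if nd.length is not None or child.length is not None:
                child.length = (nd.length or 0.0) + (child.length or 0.0)
            return child
        new = Node(nd.label, nd.length, nd.support, nd.id)
        new.annotations = dict(nd.annotations)
        for c in kept:
            new.add_child(c)
        return new

    root = rec(tree.root)
    assert root is not None
    root.parent = None
    root.length = None
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# posterior tree samples
# ---------------------------------------------------------------------------


@dataclass
class TreeSample:
    """An ordered posterior sample of trees sharing one leaf universe."""

    trees: list[PhyloTree]
    burnin_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise SampleError("burnin_fraction must be in [0, 1)")

    @property
    def n_excluded(self) -> int:
        return math.floor(self.burnin_fraction * len(self.trees))

    @property
    def post_burnin(self) -> list[PhyloTree]:
        return self.trees[self.n_excluded :]

    def __len__(self):
        return len(self.trees)


def read_tree_sample(source: str, burnin_fraction: float = 0.0) -> TreeSample:
    """Read a tree sample from newick-list text (one tree per line) or a
    NEXUS trees block (BEAST dialect; Translate resolved to labels).

    The first ``floor(burnin_fraction * N)`` trees are flagged excluded; the
    remaining trees are validated to share an identical leaf-label set, an
    offender being reported by its (0-based) index in the sample.
    """
    text = source.strip()
    if not text:
        raise SampleError("empty tree sample")
    schema = "nexus" if text.lstrip()[:6].lower() == "#nexus" else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=text,
            schema=schema,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from exc
    trees = [_from_dendropy(dt) for dt in tl]
    if not trees:
        raise SampleError("no trees found in sample")
    sample = TreeSample(trees=trees, burnin_fraction=burnin_fraction)
    post = sample.post_burnin
    if not post:
        raise SampleError("burn-in removed every tree in the sample")
    ref = post[0].leaf_set()
    for i, t in enumerate(post[1:], start=sample.n_excluded + 1):
        if t.leaf_set() != ref:
            raise SampleError(
                f"tree {i} has a different leaf set than tree {sample.n_excluded} "
                f"(after burn-in): {sorted(t.leaf_set() ^ ref)}"
            )
    return sample
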