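"""Posterior tree-sample summarization: clade frequencies and the MCC tree.

Given a posterior sample of rooted trees (e.g. a BEAST chain after
burn-in), the maximum-clade-credibility (MCC) tree is the *sampled* tree —
never a consensus construction — that maximizes the sum of log posterior
clade frequencies over its own clades.  Clades are rooted leaf-label sets
(TreeAnnotator semantics), so two trees differing only in root position
score differently.  Node supports on the returned tree are the clade
frequencies; mean clade heights are annotated when every sampled tree is
ultrametric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import SampleError
from .treecore import PhyloTree, TreeSample

__all__ = ["CladeTable", "clade_frequencies", "mcc_tree"]

_ULTRAMETRIC_RTOL = 1e-6


@dataclass
class CladeTable:
    """Rooted-clade posterior frequencies over a post-burn-in sample."""

    frequencies: dict[frozenset[str], float]
    sample_size: int

    def frequency(self, clade: frozenset[str]) -> float:
        return self.frequencies.get(frozenset(clade), 0.0)


def _clades(tree: PhyloTree) -> list[frozenset[str]]:
    """Leaf-label sets of all internal nodes (size >= 2), root included."""
    below: dict[int, frozenset[str]] = {}
    out = []
    for nd in tree.postorder():
        if nd.is_leaf:
            below[nd.id] = frozenset({nd.label})
        else:
            clade = frozenset().union(*(below[c.id] for c in nd.children))
            below[nd.id] = clade
            out.append(clade)
    return out


def clade_frequencies(sample: TreeSample) -> CladeTable:
    """Count rooted clades over the post-burn-in trees; frequency = count/N."""
    post = sample.post_burnin
    if not post:
        raise SampleError("no post-burn-in trees in sample")
    counts: dict[frozenset[str], int] = {}
    for t in post:
        for clade in _clades(t):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(post)
    return CladeTable(
        frequencies={c: k / n for c, k in counts.items()}, sample_size=n
    )


def _node_heights(tree: PhyloTree) -> dict[int, float] | None:
    """Height of every node above the tips, or None if not ultrametric."""
    height: dict[int, float] = {}
    for nd in tree.postorder():
        if nd.is_leaf:
            height[nd.id] = 0.0
            continue
        hs = []
        for c in nd.children:
            if c.length is None:
                return None
            hs.append(height[c.id] + c.length)
        hmax = max(hs)
        tol = _ULTRAMETRIC_RTOL * max(hmax, 1.0)
        if hmax - min(hs) > tol:
            return None
        height[nd.id] = hmax
    return height


def mcc_score(tree: PhyloTree, table: CladeTable) -> float:
    """Sum of log clade frequencies over the tree's rooted clades."""
    return sum(math.log(table.frequency(c)) for c in _clades(tree))


def mcc_tree(sample: TreeSample) -> PhyloTree:
    """Maximum-clade-credibility tree of a posterior sample.

    Scores every post-burn-in tree by the sum of log clade frequencies and
    returns (a copy of) the best one, ties broken by earliest sample index.
    Internal nodes are annotated with ``posterior`` (= clade frequency,
    also set as the node support) and, when every sampled tree is
    ultrametric, with ``height_mean`` — the mean MRCA height of the clade
    across the trees that contain it.
    """
    table = clade_frequencies(sample)
    post = sample.post_burnin
    best_i, best_score = 0, -math.inf
    for i, t in enumerate(post):
        s = mcc_score(t, table)
        if s > best_score:
            best_i, best_score = i, s
    result = post[best_i].copy()

    heights_per_tree = [_node_heights(t) for t in post]
    all_ultrametric = all(h is not None for h in heights_per_tree)
    clade_heights: dict[frozenset[str], list[float]] = {}
    if all_ultrametric:
        for t, h in zip(post, heights_per_tree):
            below: dict[int, frozenset[str]] = {}
            for nd in t.postorder():
                if nd.is_leaf:
                    below[nd.id] = frozenset({nd.label})
                else:
                    clade = frozenset().union(*(below[c.id] for c in nd.children))
                    below[nd.id] = clade
                    clade_heights.setdefault(clade, []).append(h[nd.id])

    below: dict[int, frozenset[str]] = {}
    for nd in result.postorder():
        if nd.is_leaf:
            below[nd.id] = frozenset({nd.label})
            continue
        clade = frozenset().union(*(below[c.id] for c in nd.children))
        below[nd.id] = clade
        freq = table.frequency(clade)
        nd.support = freq
        nd.annotations["posterior"] = f"{freq:.6g}"
        if all_ultrametric:
            hs = clade_heights[clade]
            nd.annotations["height_mean"] = f"{sum(hs) / len(hs):.6g}"
    return result
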