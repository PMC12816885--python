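"""Relative evolutionary divergence (RED) on rooted trees.

RED normalises node depth between 0 at the root and 1 at the leaves:
for a node with parent p, branch length d to p, and mean branch-length
distance u from p to all leaves descending through the node,

    red = red(p) + (1 - red(p)) * d / u.

Taxon RED is the RED of the node circumscribing the taxon's members
(their MRCA), the statistic used to compare the evolutionary depth of
a proposed genus with the rank's typical depth (e.g. the median RED of
genera across a phylum).
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Mapping, Sequence

import dendropy

from .io import leaves_under, mrca

__all__ = [
    "REDMap",
    "TaxonRed",
    "RankSummary",
    "compute_red",
    "taxon_red",
    "rank_summary",
    "core_clade_red",
    "gtdb_genus",
]


@dataclass
class REDMap:
    tree: dendropy.Tree
    red: dict[int, float]  # keyed by id(node)

    def of(self, node: dendropy.Node) -> float:
        return self.red[id(node)]


@dataclass(frozen=True)
class TaxonRed:
    """RED of a taxon's circumscribing node.

    Singleton taxa have no internal circumscribing node; they return the
    leaf's parent's RED with ``singleton`` set (explicit rather than
    interpolated along the pendant edge).
    """

    value: float
    singleton: bool
    node: dendropy.Node


@dataclass(frozen=True)
class RankSummary:
    rank: str
    values: dict[str, float]  # taxon -> RED
    median: float


def _leaf_stats(tree: dendropy.Tree) -> dict[int, tuple[int, float]]:
    """Per node: (number of descendant leaves, sum of distances to them)."""
    stats: dict[int, tuple[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[id(node)] = (1, 0.0)
        else:
            n = 0
            s = 0.0
            for ch in node.child_nodes():
                cn, cs = stats[id(ch)]
                n += cn
                s += cs + cn * (ch.edge.length or 0.0)
            stats[id(node)] = (n, s)
    return stats


def compute_red(tree: dendropy.Tree) -> REDMap:
    """RED for every node: 0 at the root, exactly 1 at every leaf,
    non-decreasing along root-to-leaf paths.

    Zero-length branches inherit the parent's RED.  An internal node
    whose entire subtree (including its own branch) has zero length has
    an undefined RED and raises.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("RED needs a tree with at least 2 leaves")
    stats = _leaf_stats(tree)
    red: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            red[id(node)] = 0.0
        elif node.is_leaf():
            red[id(node)] = 1.0
        else:
            p = red[id(node.parent_node)]
            d = node.edge.length or 0.0
            n, s = stats[id(node)]
            u = d + s / n
            if u == 0.0:
                raise ValueError(
                    f"all-zero branch lengths under internal node {node}: RED undefined")
            red[id(node)] = p + (1.0 - p) * d / u
    return REDMap(tree=tree, red=red)


def taxon_red(redmap: REDMap, tips: set[str] | Sequence[str]) -> TaxonRed:
    """RED of MRCA(tips); singleton taxa return the leaf's parent's RED
    with the singleton flag set."""
    tips = sorted(set(tips))
    if not tips:
        raise ValueError("tips must be non-empty")
    node = mrca(redmap.tree, tips)
    if node.is_leaf():
        parent = node.parent_node
        if parent is None:
            raise ValueError("singleton taxon at the root")
        return TaxonRed(value=redmap.of(parent), singleton=True, node=parent)
    return TaxonRed(value=redmap.of(node), singleton=False, node=node)


def rank_summary(redmap: REDMap, taxa: Mapping[str, set[str]],
                 rank: str = "genus") -> RankSummary:
    """Median RED over the taxa of one rank (even counts average the
    central pair)."""
    if not taxa:
        raise ValueError("need at least one taxon")
    values = {name: taxon_red(redmap, tips).value for name, tips in sorted(taxa.items())}
    return RankSummary(rank=rank, values=values, median=float(median(values.values())))


def core_clade_red(redmap: REDMap, named_tips: set[str] | Sequence[str]) -> TaxonRed:
    """RED of the smallest clade spanning the named (validly published)
    members — the core-clade statistic; identical to :func:`taxon_red`."""
    return taxon_red(redmap, named_tips)


def gtdb_genus(taxonomy: str) -> str | None:
    """Extract the genus from a GTDB-style taxonomy string (``g__`` field)."""
    for part in taxonomy.split(";"):
        part = part.strip()
        if part.startswith("g__"):
            return part[3:] or None
    return None
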