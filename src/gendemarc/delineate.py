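"""Candidate genus groups from joint AAI + POCP criteria and monophyly.

Genome pairs passing both thresholds form the edges of a criterion
graph; its connected components are candidate genera.  Each component
is tested for monophyly on the phylogenomic tree, and non-monophyletic
components are resolved by greedily removing the member whose removal
most reduces the intruder count (deterministic tie-break), with removed
genomes reported as explicit exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import networkx as nx

from .homology import PairMetrics
from .io import leaves_under, mrca

__all__ = [
    "CriterionGraph",
    "MonophylyResult",
    "GenusPartition",
    "build_graph",
    "components",
    "monophyly_test",
    "delineate",
]


@dataclass
class CriterionGraph:
    graph: nx.Graph
    aai_threshold: float
    pocp_threshold: float

    @property
    def vertices(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}


@dataclass(frozen=True)
class MonophylyResult:
    is_monophyletic: bool
    mrca: dendropy.Node
    intruders: frozenset[str]


@dataclass
class GenusPartition:
    """Final grouping: disjoint genus groups plus explicit exclusions.

    ``excluded`` maps genome id -> reason code; groups and exclusions
    together cover every graph vertex exactly once.
    """

    groups: list[set[str]]
    excluded: dict[str, str] = field(default_factory=dict)
    verdicts: list[MonophylyResult] = field(default_factory=list)

    def group_of(self, genome: str) -> Optional[int]:
        for i, g in enumerate(self.groups):
            if genome in g:
                return i
        return None


def build_graph(metrics: Sequence[PairMetrics], aai_threshold: float,
                pocp_threshold: float = 50.0) -> CriterionGraph:
    """Edge iff AAI >= aai_threshold and POCP >= pocp_threshold (inclusive).

    Pairs with undefined AAI contribute no edge.  Duplicate rows for the
    same unordered pair are rejected.
    """
    g = nx.Graph()
    seen: set[frozenset] = set()
    for m in metrics:
        if m.genome_a == m.genome_b:
            raise ValueError(f"self-pair row for {m.genome_a!r}")
        key = frozenset((m.genome_a, m.genome_b))
        if key in seen:
            raise ValueError(f"duplicate pair row: {m.genome_a!r}/{m.genome_b!r}")
        seen.add(key)
        g.add_node(m.genome_a)
        g.add_node(m.genome_b)
        if m.aai is not None and m.aai >= aai_threshold and m.pocp >= pocp_threshold:
            g.add_edge(m.genome_a, m.genome_b)
    return CriterionGraph(graph=g, aai_threshold=aai_threshold,
                          pocp_threshold=pocp_threshold)


def components(cgraph: CriterionGraph) -> list[set[str]]:
    """Connected components (singletons included), ordered by smallest member."""
    comps = [set(c) for c in nx.connected_components(cgraph.graph)]
    comps.sort(key=lambda c: min(c))
    return comps


def monophyly_test(tree: dendropy.Tree, tips: set[str]) -> MonophylyResult:
    """Are *tips* exactly the leaves of their MRCA's clade?

    Singleton sets are monophyletic by definition.  Unknown tips raise
    ``KeyError`` naming the tip.
    """
    if not tips:
        raise ValueError("tips must be non-empty")
    node = mrca(tree, sorted(tips))
    intruders = frozenset(leaves_under(node) - tips)
    return MonophylyResult(is_monophyletic=not intruders, mrca=node,
                           intruders=intruders)


def _resolve_component(tree: dendropy.Tree, comp: set[str]
                       ) -> tuple[set[str], list[str], MonophylyResult]:
    """Greedy removal until the component is monophyletic or a singleton.

    At each step, remove the member whose removal leaves the fewest
    intruders; ties break toward the lexicographically last id.
    """
    current = set(comp)
    removed: list[str] = []
    verdict = monophyly_test(tree, current)
    while not verdict.is_monophyletic and len(current) > 1:
        best_victim = None
        best_count = None
        for v in sorted(current):
            rest = current - {v}
            n_intr = len(monophyly_test(tree, rest).intruders)
            if best_count is None or n_intr < best_count or (
                    n_intr == best_count and v > best_victim):
                best_victim, best_count = v, n_intr
        current.remove(best_victim)
        removed.append(best_victim)
        verdict = monophyly_test(tree, current)
    return current, removed, verdict


def delineate(tree: dendropy.Tree, cgraph: CriterionGraph) -> GenusPartition:
    """Partition graph vertices into monophyletic genus groups + exclusions."""
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = cgraph.vertices - tree_leaves
    if missing:
        raise KeyError(f"graph vertices absent from tree: {sorted(missing)}")
    partition = GenusPartition(groups=[])
    for comp in components(cgraph):
        kept, removed, verdict = _resolve_component(tree, comp)
        partition.groups.append(kept)
        partition.verdicts.append(verdict)
        for v in removed:
            partition.excluded[v] = "breaks_monophyly"
    return partition
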