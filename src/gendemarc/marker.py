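"""Marker-gene clade membership and phenotype concordance.

Given a gene tree (e.g. tryptophanase / tnaA) containing sequences from
the study genomes plus experimentally validated reference sequences,
the validated clade is the MRCA of the references.  A genome is a clade
member when at least one of its genes falls inside that clade, and
membership is cross-tabulated against a binary phenotype (e.g. indole
production) to quantify concordance.

Phenotypes are three-valued (positive / negative / variable); genomes
with a "variable" phenotype are excluded from the counts by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

from .homology import global_protein_identity
from .io import SequenceRecord, leaves_under, mrca

__all__ = [
    "GeneTree",
    "ConcordanceTable",
    "validated_clade",
    "genome_membership",
    "concordance",
    "neighbor_joining_tree",
    "normalize_phenotype",
]

POSITIVE = "positive"
NEGATIVE = "negative"
VARIABLE = "variable"


@dataclass
class GeneTree:
    """Gene tree whose leaves are gene ids, each mapped to a genome
    (or absent for pure reference sequences)."""

    tree: dendropy.Tree
    gene_to_genome: dict[str, str]
    reference_ids: frozenset[str]

    def __post_init__(self) -> None:
        leaf_ids = {lf.taxon.label for lf in self.tree.leaf_node_iter()}
        missing = set(self.reference_ids) - leaf_ids
        if missing:
            raise KeyError(f"reference ids absent from gene tree: {sorted(missing)}")
        self.reference_ids = frozenset(self.reference_ids)


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 cross-tabulation of clade membership vs phenotype.

    ``n11`` = member & positive, ``n10`` = member & negative,
    ``n01`` = non-member & positive, ``n00`` = non-member & negative.
    ``n_absent_negative`` tallies phenotype-negative genomes with no
    gene in the tree at all (absent, distinct from non-member);
    ``n_absent_positive`` the symmetric case.
    """

    n11: int
    n10: int
    n01: int
    n00: int
    n_absent_negative: int = 0
    n_absent_positive: int = 0

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def agreement(self) -> float:
        if self.total == 0:
            raise ValueError("no genome has both a membership and a phenotype call")
        return (self.n11 + self.n00) / self.total


def validated_clade(gtree: GeneTree) -> dendropy.Node:
    """MRCA of the experimentally validated reference sequences.

    A single reference returns its leaf's parent (singleton case); a
    reference set spanning the whole tree returns the root with a
    warning, since a root-wide clade carries no signal about which
    genes share the validated function.
    """
    if not gtree.reference_ids:
        raise ValueError("gene tree has no reference ids")
    node = mrca(gtree.tree, sorted(gtree.reference_ids))
    if node.is_leaf():
        if node.parent_node is None:
            raise ValueError("single-leaf gene tree")
        return node.parent_node
    if node.parent_node is None:
        warnings.warn("validated clade spans the gene-tree root", stacklevel=2)
    return node


def genome_membership(gtree: GeneTree, clade: dendropy.Node) -> dict[str, bool]:
    """genome id -> True iff >= 1 of its genes is a leaf under *clade*.

    Genomes with no gene in the tree are absent from the map (absence
    is distinct from False).
    """
    in_clade = leaves_under(clade)
    membership: dict[str, bool] = {}
    for lf in gtree.tree.leaf_node_iter():
        gene = lf.taxon.label
        genome = gtree.gene_to_genome.get(gene)
        if genome is None:
            continue
        membership[genome] = membership.get(genome, False) or (gene in in_clade)
    return membership


def normalize_phenotype(value) -> str:
    """Coerce bools/strings to the three-valued phenotype coding."""
    if value is True:
        return POSITIVE
    if value is False:
        return NEGATIVE
    v = str(value).strip().lower()
    if v in ("positive", "pos", "+", "true", "1"):
        return POSITIVE
    if v in ("negative", "neg", "-", "false", "0"):
        return NEGATIVE
    if v in ("variable", "var", "v"):
        return VARIABLE
    raise ValueError(f"unrecognised phenotype value {value!r}")


def concordance(membership: Mapping[str, bool],
                phenotype: Mapping[str, object],
                include_variable: bool = False) -> ConcordanceTable:
    """Cross-tabulate clade membership against phenotype.

    Counts cover genomes present in both maps; "variable" phenotypes are
    excluded unless ``include_variable`` (then counted as positive).
    Genomes with a phenotype but no gene in the tree are tallied in the
    absent/<phenotype> side channels.
    """
    n11 = n10 = n01 = n00 = absent_neg = absent_pos = 0
    for genome, raw in phenotype.items():
        ph = normalize_phenotype(raw)
        if ph == VARIABLE:
            if not include_variable:
                continue
            ph = POSITIVE
        pos = ph == POSITIVE
        if genome not in membership:
            if pos:
                absent_pos += 1
            else:
                absent_neg += 1
            continue
        member = membership[genome]
        if member and pos:
            n11 += 1
        elif member and not pos:
            n10 += 1
        elif not member and pos:
            n01 += 1
        else:
            n00 += 1
    return ConcordanceTable(n11=n11, n10=n10, n01=n01, n00=n00,
                            n_absent_negative=absent_neg,
                            n_absent_positive=absent_pos)


def neighbor_joining_tree(records: Sequence[SequenceRecord]) -> dendropy.Tree:
    """Neighbor-joining gene tree from pairwise global identities,
    midpoint-rooted.  A convenience for synthetic tests; real analyses
    should supply a maximum-likelihood gene tree as input.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    ids = [r.id for r in records]
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 sequences")
    dm = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = 100.0 - global_protein_identity(records[i], records[j])
            dm[i][j] = dm[j][i] = d
    tree_skbio = nj(DistanceMatrix(dm, ids))
    import io as _io
    buf = _io.StringIO()
    tree_skbio.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                             preserve_underscores=True)
    tree.reroot_at_midpoint(update_bipartitions=False)
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = True
    return tree
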