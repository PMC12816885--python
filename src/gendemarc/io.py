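"""Sequence and tree input/output plus elementary sequence statistics.

FASTA records are validated against a declared alphabet (amino acid or
nucleotide); Newick trees are parsed into rooted :class:`dendropy.Tree`
objects with branch lengths.  Pairwise nucleotide identity uses global
Needleman-Wunsch alignment with an explicit, documented scoring scheme so
that reported 16S-style similarities are reproducible.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import Align, SeqIO

__all__ = [
    "SequenceRecord",
    "FastaError",
    "NewickError",
    "UndefinedValueError",
    "NucleotideAlignParams",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "gc_content",
    "genome_size",
    "global_identity",
    "leaf_labels",
    "mrca",
    "leaves_under",
]

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NT_ALPHABET = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed or invalid FASTA content."""


class NewickError(ValueError):
    """Malformed Newick text."""


class UndefinedValueError(ValueError):
    """A statistic is undefined for the given input (e.g. no unambiguous bases)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: unique id, free-text description, residue string."""

    id: str
    description: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class NucleotideAlignParams:
    """Scoring for global nucleotide identity.

    Defaults: match +1, mismatch -1, gap -2 (linear), terminal gaps
    penalized like internal ones.  Identity conventions differ between
    aligners, so small deviations from values produced by other tools
    (Clustal Omega, blastn) are expected.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def _validate_seq(seq: str, alphabet: str, record_id: str) -> str:
    allowed = AA_ALPHABET if alphabet == "aa" else NT_ALPHABET
    seq = seq.upper()
    if alphabet == "nt":
        seq = seq.replace("U", "T")
    for pos, ch in enumerate(seq):
        if ch not in allowed:
            raise FastaError(
                f"illegal character {ch!r} at position {pos + 1} of record "
                f"{record_id!r} for alphabet {alphabet!r}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: str = "aa") -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Parameters
    ----------
    path:
        FASTA file (wrapped or unwrapped, multi-record).
    alphabet:
        ``"aa"`` or ``"nt"``.  Sequences are uppercased; for nucleotides,
        U is mapped to T.  Gap characters are rejected.

    Raises
    ------
    FastaError
        On duplicate ids (naming the id), illegal characters (with
        position) or empty sequences.
    """
    if alphabet not in ("aa", "nt"):
        raise ValueError(f"alphabet must be 'aa' or 'nt', got {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaError("record with empty id")
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise FastaError(f"record {rec.id!r} has an empty sequence")
        seq = _validate_seq(seq, alphabet, rec.id)
        records.append(SequenceRecord(id=rec.id, description=rec.description, seq=seq))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence lines at *width* columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse Newick text (or a path to it) into a rooted tree.

    Branch lengths are preserved; edges without a length get 0.0.  Leaf
    labels must be unique.  Internal-node labels are kept verbatim.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and not source.rstrip().endswith(";")
                                    and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickError("Newick text must end with ';' "
                          f"(offset {len(stripped)})")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse error: {exc}") from exc
    tree.is_rooted = True
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate leaf labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
        elif edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")
    tree.seed_node.edge.length = 0.0
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick with branch lengths (round-trip safe)."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    """Leaf labels in tree order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def mrca(tree: dendropy.Tree, labels: Sequence[str]) -> dendropy.Node:
    """Most recent common ancestor of the named leaves.

    Raises ``KeyError`` naming the first unknown label.
    """
    by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    nodes = []
    for lab in labels:
        if lab not in by_label:
            raise KeyError(f"unknown leaf label {lab!r}")
        nodes.append(by_label[lab])
    if len(nodes) == 1:
        return nodes[0]
    # walk root-paths: the MRCA is the deepest node common to all paths
    paths = []
    for node in nodes:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(set(path))
    node = nodes[0]
    while node is not None:
        if all(node in p for p in paths):
            return node
        node = node.parent_node
    raise RuntimeError("no common ancestor found (disconnected tree)")


def leaves_under(node: dendropy.Node) -> set[str]:
    """Labels of all leaves in the clade rooted at *node*."""
    return {lf.taxon.label for lf in node.leaf_iter()}


def gc_content(records: Sequence[SequenceRecord]) -> float:
    """G+C percentage pooled over all records, to 0.1 precision.

    Ambiguity characters (N) are excluded from both numerator and
    denominator.
    """
    gc = 0
    total = 0
    for rec in records:
        for ch in rec.seq:
            if ch in "GC":
                gc += 1
                total += 1
            elif ch in "AT":
                total += 1
    if total == 0:
        raise UndefinedValueError("G+C content undefined: no unambiguous bases")
    return round(100.0 * gc / total, 1)


def genome_size(records: Sequence[SequenceRecord]) -> int:
    """Total assembly length in bp (sum of record lengths)."""
    return sum(len(r) for r in records)


def _nt_aligner(params: NucleotideAlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap
    al.extend_gap_score = params.gap
    return al


def global_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    params: NucleotideAlignParams | None = None,
) -> float:
    """Percent identity from a global Needleman-Wunsch alignment.

    Identity = 100 x matches / alignment columns, with gap columns counted
    in the denominator and terminal gaps penalized.  The pair is put in a
    canonical order before aligning so the result is exactly symmetric.
    """
    if not a.seq or not b.seq:
        raise ValueError("cannot align an empty sequence")
    params = params or NucleotideAlignParams()
    x, y = sorted((a.seq, b.seq))
    aln = _nt_aligner(params).align(x, y)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length
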