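"""Pairwise proteome comparison: local alignment search, reciprocal best
hits, AAI, POCP and marker-subset AAI.

The search stage is Smith-Waterman under BLOSUM62 with affine gaps
(open 11, extend 1), executed through Biopython's C ``PairwiseAligner``.
Statistical significance uses the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with the ungapped constants
lambda = 0.3176, K = 0.134 applied to the gapped score as an
approximation; ``m`` and ``n`` are the two full sequence lengths.

AAI is the mean identity over reciprocal best-hit pairs whose hits pass
identity >= 40 %, query coverage >= 50 % and e-value <= 1e-5 in both
directions.  POCP counts, for each proteome, the proteins with at least
one hit in the partner satisfying e-value < 1e-5, identity > 40 % and an
alignable region covering > 50 % of the query length, and reports
``100 * (C1 + C2) / (T1 + T2)``.

An exact all-vs-all search is quadratic in proteome size; a k-mer
prefilter (candidate subject must share at least ``min_shared_kmers``
exact k-mers with the query) plus a raw-score screen derived from the
e-value ceiling keep desk-scale runs fast.  Setting
``min_shared_kmers=0`` disables the prefilter and makes the search
exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

__all__ = [
    "AlignParams",
    "Proteome",
    "AlignmentHit",
    "PairMetrics",
    "UndefinedMetricError",
    "align_pair",
    "best_hits",
    "reciprocal_best_hits",
    "aai",
    "pocp",
    "pair_metrics",
    "marker_aai",
    "global_protein_identity",
]


class UndefinedMetricError(ValueError):
    """A pairwise metric has no defined value (e.g. AAI with zero RBH pairs)."""


@dataclass(frozen=True)
class AlignParams:
    """Alignment scoring and hit-filter parameters.

    The AAI filters (identity >= 40, coverage >= 50, e <= 1e-5) follow
    EzAAI defaults; the POCP filters (e < 1e-5, identity > 40, alignable
    region > 50 % of query) follow the POCP definition.  Note the strict
    vs non-strict inequalities differ between the two conventions.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.3176
    karlin_k: float = 0.134
    aai_min_identity: float = 40.0
    aai_min_coverage: float = 50.0
    aai_max_evalue: float = 1e-5
    pocp_max_evalue: float = 1e-5
    pocp_min_identity: float = 40.0
    pocp_min_coverage: float = 50.0
    kmer_size: int = 4
    min_shared_kmers: int = 1  # 0 disables the prefilter (exhaustive search)


@dataclass
class Proteome:
    """A genome's predicted proteins; the unit of all pairwise metrics."""

    genome_id: str
    proteins: list[SequenceRecord]
    _kmer_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"proteome {self.genome_id!r} has no proteins")
        ids = [p.id for p in self.proteins]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids in {self.genome_id!r}: {dup}")

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    def kmer_sets(self, k: int) -> list[frozenset]:
        if k not in self._kmer_cache:
            self._kmer_cache[k] = [
                frozenset(p.seq[i : i + k] for i in range(len(p.seq) - k + 1))
                for p in self.proteins
            ]
        return self._kmer_cache[k]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    identity: float  # percent over aligned columns
    aligned_length: int  # alignment columns (incl. internal gaps)
    query_coverage: float  # percent of query length spanned
    bit_score: float
    e_value: float
    score: float  # raw Smith-Waterman score

    def __post_init__(self) -> None:
        assert 0.0 <= self.identity <= 100.0
        assert self.e_value >= 0.0


@dataclass(frozen=True)
class PairMetrics:
    """AAI + POCP and supporting counts for one unordered genome pair.

    ``aai`` is ``None`` (with ``aai_defined`` False) when no reciprocal
    best-hit pair passes the filters; it is never a silent NaN.
    """

    genome_a: str
    genome_b: str
    aai: Optional[float]
    n_rbh: int
    pocp: float
    c_a: int
    c_b: int
    t_a: int
    t_b: int

    @property
    def aai_defined(self) -> bool:
        return self.aai is not None

    def __post_init__(self) -> None:
        expected = 100.0 * (self.c_a + self.c_b) / (self.t_a + self.t_b)
        assert abs(self.pocp - expected) < 1e-9


@lru_cache(maxsize=8)
def _protein_aligner(matrix: str, gap_open: float, gap_extend: float,
                     mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.mode = mode
    al.open_gap_score = -abs(gap_open)
    al.extend_gap_score = -abs(gap_extend)
    return al


def _evalue(score: float, m: int, n: int, params: AlignParams) -> float:
    return params.karlin_k * m * n * math.exp(-params.karlin_lambda * score)


def _bit_score(score: float, params: AlignParams) -> float:
    return (params.karlin_lambda * score - math.log(params.karlin_k)) / math.log(2.0)


def _min_useful_score(m: int, n: int, params: AlignParams) -> float:
    """Raw score below which E > both e-value ceilings, so no filter can pass."""
    ceiling = max(params.aai_max_evalue, params.pocp_max_evalue)
    return math.log(params.karlin_k * m * n / ceiling) / params.karlin_lambda


def _hit_from_alignment(aln, score: float, query: SequenceRecord,
                        subject: SequenceRecord, params: AlignParams) -> AlignmentHit:
    counts = aln.counts()
    columns = aln.length
    q_segs = aln.aligned[0]  # align(query, subject): target = query
    q_span = int(q_segs[-1][1] - q_segs[0][0])
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        identity=100.0 * counts.identities / columns,
        aligned_length=int(columns),
        query_coverage=100.0 * q_span / len(query),
        bit_score=_bit_score(score, params),
        e_value=_evalue(score, len(query), len(subject), params),
        score=score,
    )


def align_pair(query: SequenceRecord, subject: SequenceRecord,
               params: AlignParams | None = None) -> Optional[AlignmentHit]:
    """Optimal local alignment of two proteins, or ``None`` if its score <= 0."""
    if not query.seq or not subject.seq:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignParams()
    aligner = _protein_aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    score = aligner.score(query.seq, subject.seq)
    if score <= 0:
        return None
    aln = aligner.align(query.seq, subject.seq)[0]
    return _hit_from_alignment(aln, score, query, subject, params)


@dataclass(frozen=True)
class _SymmetricHit:
    """One optimal local alignment between protein i of A and j of B.

    Score, identity and aligned length are direction-free; coverage is
    stored for both directions (denominator = that side's length).
    """

    i: int
    j: int
    score: float
    identity: float
    aligned_length: int
    cov_a: float
    cov_b: float
    e_value: float
    bit_score: float


def _search_pair(a: Proteome, b: Proteome, params: AlignParams) -> list[_SymmetricHit]:
    """All candidate-pair optimal local alignments that can matter.

    Alignments with raw score below the e-value-derived screen are
    dropped: they cannot pass either the AAI or POCP e-value ceiling.
    """
    aligner = _protein_aligner(params.matrix, params.gap_open, params.gap_extend, "local")
    use_prefilter = params.min_shared_kmers > 0
    if use_prefilter:
        ka = a.kmer_sets(params.kmer_size)
        kb = b.kmer_sets(params.kmer_size)
    hits: list[_SymmetricHit] = []
    for i, pa in enumerate(a.proteins):
        for j, pb in enumerate(b.proteins):
            if use_prefilter:
                shared = len(ka[i] & kb[j])
                if shared < params.min_shared_kmers:
                    continue
            score = aligner.score(pa.seq, pb.seq)
            if score <= 0 or score < _min_useful_score(len(pa), len(pb), params):
                continue
            aln = aligner.align(pa.seq, pb.seq)[0]
            counts = aln.counts()
            columns = aln.length
            segs_a, segs_b = aln.aligned
            span_a = int(segs_a[-1][1] - segs_a[0][0])
            span_b = int(segs_b[-1][1] - segs_b[0][0])
            hits.append(_SymmetricHit(
                i=i, j=j, score=score,
                identity=100.0 * counts.identities / columns,
                aligned_length=int(columns),
                cov_a=100.0 * span_a / len(pa),
                cov_b=100.0 * span_b / len(pb),
                e_value=_evalue(score, len(pa), len(pb), params),
                bit_score=_bit_score(score, params),
            ))
    return hits


def _directional_hit(h: _SymmetricHit, a: Proteome, b: Proteome,
                     forward: bool) -> AlignmentHit:
    if forward:
        return AlignmentHit(a.proteins[h.i].id, b.proteins[h.j].id, h.identity,
                            h.aligned_length, h.cov_a, h.bit_score, h.e_value, h.score)
    return AlignmentHit(b.proteins[h.j].id, a.proteins[h.i].id, h.identity,
                        h.aligned_length, h.cov_b, h.bit_score, h.e_value, h.score)


def _best_by_query(hits: list[_SymmetricHit], a: Proteome, b: Proteome,
                   forward: bool, max_evalue: float) -> dict[str, AlignmentHit]:
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        if h.e_value > max_evalue:
            continue
        d = _directional_hit(h, a, b, forward)
        prev = best.get(d.query_id)
        if (prev is None or d.bit_score > prev.bit_score
                or (d.bit_score == prev.bit_score and d.subject_id < prev.subject_id)):
            best[d.query_id] = d
    return best


def best_hits(a: Proteome, b: Proteome,
              params: AlignParams | None = None) -> dict[str, AlignmentHit]:
    """For each protein of *a*, its highest-bit-score hit in *b* passing the
    e-value ceiling; ties broken toward the lexicographically smallest
    subject id."""
    params = params or AlignParams()
    hits = _search_pair(a, b, params)
    return _best_by_query(hits, a, b, True, params.aai_max_evalue)


def reciprocal_best_hits(ab: dict[str, AlignmentHit],
                         ba: dict[str, AlignmentHit]) -> list[tuple[str, str, float]]:
    """Pairs (x, y) with ab[x] = y and ba[y] = x; identity is the mean of the
    two directional identities."""
    out = []
    for x, hx in ab.items():
        y = hx.subject_id
        hy = ba.get(y)
        if hy is not None and hy.subject_id == x:
            out.append((x, y, 0.5 * (hx.identity + hy.identity)))
    out.sort()
    return out


def _rbh_identities(hits: list[_SymmetricHit], a: Proteome, b: Proteome,
                    params: AlignParams) -> list[float]:
    ab = _best_by_query(hits, a, b, True, params.aai_max_evalue)
    ba = _best_by_query(hits, a, b, False, params.aai_max_evalue)
    rbh = reciprocal_best_hits(ab, ba)
    ids = []
    for x, y, ident in rbh:
        hx, hy = ab[x], ba[y]
        ok = all(
            h.identity >= params.aai_min_identity
            and h.query_coverage >= params.aai_min_coverage
            and h.e_value <= params.aai_max_evalue
            for h in (hx, hy)
        )
        if ok:
            ids.append(ident)
    return ids


def _pocp_counts(hits: list[_SymmetricHit], a: Proteome, b: Proteome,
                 params: AlignParams) -> tuple[int, int]:
    conserved_a: set[int] = set()
    conserved_b: set[int] = set()
    for h in hits:
        if not (h.e_value < params.pocp_max_evalue
                and h.identity > params.pocp_min_identity):
            continue
        if h.cov_a > params.pocp_min_coverage:
            conserved_a.add(h.i)
        if h.cov_b > params.pocp_min_coverage:
            conserved_b.add(h.j)
    return len(conserved_a), len(conserved_b)


def aai(a: Proteome, b: Proteome,
        params: AlignParams | None = None) -> tuple[Optional[float], int]:
    """AAI and the number of filtered RBH pairs it averages; ``(None, 0)``
    when no pair passes (undefined, flagged rather than NaN)."""
    params = params or AlignParams()
    ids = _rbh_identities(_search_pair(a, b, params), a, b, params)
    if not ids:
        return None, 0
    return sum(ids) / len(ids), len(ids)


def pocp(a: Proteome, b: Proteome,
         params: AlignParams | None = None) -> tuple[float, int, int, int, int]:
    """POCP with its supporting counts ``(pocp, C1, C2, T1, T2)``."""
    params = params or AlignParams()
    c_a, c_b = _pocp_counts(_search_pair(a, b, params), a, b, params)
    value = 100.0 * (c_a + c_b) / (a.n_proteins + b.n_proteins)
    return value, c_a, c_b, a.n_proteins, b.n_proteins


def pair_metrics(a: Proteome, b: Proteome,
                 params: AlignParams | None = None) -> PairMetrics:
    """AAI and POCP for one genome pair from a single search pass."""
    params = params or AlignParams()
    hits = _search_pair(a, b, params)
    ids = _rbh_identities(hits, a, b, params)
    c_a, c_b = _pocp_counts(hits, a, b, params)
    return PairMetrics(
        genome_a=a.genome_id,
        genome_b=b.genome_id,
        aai=(sum(ids) / len(ids)) if ids else None,
        n_rbh=len(ids),
        pocp=100.0 * (c_a + c_b) / (a.n_proteins + b.n_proteins),
        c_a=c_a, c_b=c_b, t_a=a.n_proteins, t_b=b.n_proteins,
    )


def global_protein_identity(a: SequenceRecord, b: SequenceRecord,
                            params: AlignParams | None = None) -> float:
    """Percent identity of the global BLOSUM62 alignment (gap columns in the
    denominator); exactly symmetric via canonical pair ordering."""
    if not a.seq or not b.seq:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignParams()
    aligner = _protein_aligner(params.matrix, params.gap_open, params.gap_extend, "global")
    x, y = sorted((a.seq, b.seq))
    aln = aligner.align(x, y)[0]
    return 100.0 * aln.counts().identities / aln.length


def marker_aai(a: Proteome, b: Proteome,
               marker_map: dict[str, dict[str, str]],
               params: AlignParams | None = None) -> tuple[Optional[float], int]:
    """Mean global identity over marker genes single-copy in both genomes.

    ``marker_map`` maps genome id -> {marker name -> protein id}.  Returns
    ``(mean identity, n shared markers)``; ``(None, 0)`` when the genomes
    share no marker.
    """
    map_a = marker_map.get(a.genome_id, {})
    map_b = marker_map.get(b.genome_id, {})
    shared = sorted(set(map_a) & set(map_b))
    if not shared:
        return None, 0
    prot_a = {p.id: p for p in a.proteins}
    prot_b = {p.id: p for p in b.proteins}
    idents = []
    for marker in shared:
        pa, pb = map_a[marker], map_b[marker]
        if pa not in prot_a:
            raise KeyError(f"marker {marker!r}: protein {pa!r} not in {a.genome_id!r}")
        if pb not in prot_b:
            raise KeyError(f"marker {marker!r}: protein {pb!r} not in {b.genome_id!r}")
        idents.append(global_protein_identity(prot_a[pa], prot_b[pb], params))
    return sum(idents) / len(idents), len(shared)
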