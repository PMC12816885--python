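from __future__ import annotations

import math
import random

import pytest

from conftest import EXHAUSTIVE, mutate, random_protein
from _oracles import sw_affine_oracle

from gendemarc.homology import (
    AlignParams,
    Proteome,
    aai,
    align_pair,
    best_hits,
    marker_aai,
    pair_metrics,
    pocp,
    reciprocal_best_hits,
)
from gendemarc.io import SequenceRecord


def _rec(i, seq):
    return SequenceRecord(i, "", seq)


class TestAlignPair:
    def test_self_alignment_is_full_identity(self):
        rng = random.Random(0)
        p = _rec("p", random_protein(rng, 100))
        hit = align_pair(p, p)
        assert hit.identity == 100.0
        assert hit.query_coverage == 100.0

    def test_no_positive_scoring_alignment_returns_none(self):
        assert align_pair(_rec("q", "MKV"), _rec("s", "AAAA")) is None

    def test_planted_substitutions_identity(self):
        rng = random.Random(1)
        base = random_protein(rng, 50)
        other = mutate(base, 5, rng)
        hit = align_pair(_rec("q", base), _rec("s", other))
        # full-length ungapped alignment expected for 90 % identity
        score, co_optimal = sw_affine_oracle(base, other)
        assert hit.score == score
        assert (round(hit.identity * hit.aligned_length / 100),
                hit.aligned_length) in co_optimal

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_exhaustive_dp(self, seed):
        """Score exact; identity within the co-optimal alignment set."""
        rng = random.Random(seed)
        a = random_protein(rng, rng.randint(20, 60))
        if seed % 2:
            b = mutate(a, rng.randint(2, 12), rng)
        else:
            b = random_protein(rng, rng.randint(20, 60))
        hit = align_pair(_rec("q", a), _rec("s", b))
        score, co_optimal = sw_affine_oracle(a, b)
        if hit is None:
            assert score == 0.0
            return
        assert hit.score == pytest.approx(score, abs=1e-9)
        idents = round(hit.identity * hit.aligned_length / 100)
        assert (idents, hit.aligned_length) in co_optimal

    def test_empty_sequence_error(self):
        with pytest.raises(ValueError):
            align_pair(_rec("q", ""), _rec("s", "MKV"))

    def test_evalue_is_karlin_altschul_form(self):
        rng = random.Random(3)
        p = _rec("p", random_protein(rng, 80))
        hit = align_pair(p, p)
        params = AlignParams()
        expect = params.karlin_k * 80 * 80 * math.exp(-params.karlin_lambda * hit.score)
        assert hit.e_value == pytest.approx(expect, rel=1e-12)


class TestBestHits:
    def test_exact_copies_map_to_themselves(self):
        rng = random.Random(7)
        seqs = [random_protein(rng, 60) for _ in range(10)]
        a = Proteome("a", [_rec(f"a{i}", s) for i, s in enumerate(seqs)])
        b = Proteome("b", [_rec(f"b{i}", s) for i, s in enumerate(seqs)])
        hits = best_hits(a, b, EXHAUSTIVE)
        assert len(hits) == 10
        for i in range(10):
            assert hits[f"a{i}"].subject_id == f"b{i}"
            assert hits[f"a{i}"].identity == 100.0

    def test_unmatched_protein_absent_from_map(self):
        rng = random.Random(8)
        a = Proteome("a", [_rec("a0", random_protein(rng, 60)),
                           _rec("a1", "MKVMKVMKV")])
        b = Proteome("b", [_rec("b0", a.proteins[0].seq)])
        hits = best_hits(a, b, EXHAUSTIVE)
        assert "a0" in hits and "a1" not in hits

    def test_equal_score_tie_breaks_to_smaller_subject_id(self):
        rng = random.Random(9)
        s = random_protein(rng, 60)
        a = Proteome("a", [_rec("a0", s)])
        b = Proteome("b", [_rec("b9", s), _rec("b1", s)])
        hits = best_hits(a, b, EXHAUSTIVE)
        assert hits["a0"].subject_id == "b1"


class TestReciprocalBestHits:
    def test_mutual_copies_all_recovered(self):
        rng = random.Random(10)
        seqs = [random_protein(rng, 60) for _ in range(10)]
        a = Proteome("a", [_rec(f"a{i}", s) for i, s in enumerate(seqs)])
        b = Proteome("b", [_rec(f"b{i}", s) for i, s in enumerate(seqs)])
        rbh = reciprocal_best_hits(best_hits(a, b, EXHAUSTIVE),
                                   best_hits(b, a, EXHAUSTIVE))
        assert len(rbh) == 10
        assert all(ident == 100.0 for _, _, ident in rbh)

    def test_one_way_hit_excluded_and_mean_identity(self):
        from gendemarc.homology import AlignmentHit
        h = lambda q, s, i: AlignmentHit(q, s, i, 50, 100.0, 50.0, 1e-30, 100.0)
        ab = {"x": h("x", "y", 80.0), "z": h("z", "y", 70.0)}
        ba = {"y": h("y", "x", 82.0)}
        rbh = reciprocal_best_hits(ab, ba)
        assert rbh == [("x", "y", 81.0)]


class TestAAIAndPOCP:
    def test_identical_proteomes_aai_and_pocp_100(self):
        rng = random.Random(11)
        prots = [_rec(f"p{i}", random_protein(rng, 80)) for i in range(8)]
        a = Proteome("a", prots)
        b = Proteome("b", list(prots))
        value, n_rbh = aai(a, b, EXHAUSTIVE)
        assert value == 100.0 and n_rbh == 8
        p, c1, c2, t1, t2 = pocp(a, b, EXHAUSTIVE)
        assert p == 100.0 and (c1, c2, t1, t2) == (8, 8, 8, 8)

    def test_self_comparison_is_100(self, toy_proteomes):
        a, _ = toy_proteomes
        value, _ = aai(a, a, EXHAUSTIVE)
        assert value == 100.0
        assert pocp(a, a, EXHAUSTIVE)[0] == 100.0

    def test_unrelated_proteomes_undefined_aai_and_pocp_0(self):
        rng = random.Random(12)
        a = Proteome("a", [_rec(f"a{i}", random_protein(rng, 50))
                           for i in range(4)])
        b = Proteome("b", [_rec(f"b{i}", random_protein(rng, 50))
                           for i in range(4)])
        value, n_rbh = aai(a, b, EXHAUSTIVE)
        assert value is None and n_rbh == 0
        assert pocp(a, b, EXHAUSTIVE)[0] == 0.0

    def test_symmetry_exact(self, toy_proteomes):
        a, b = toy_proteomes
        assert aai(a, b, EXHAUSTIVE) == aai(b, a, EXHAUSTIVE)
        pa = pocp(a, b, EXHAUSTIVE)
        pb = pocp(b, a, EXHAUSTIVE)
        assert pa[0] == pb[0] and (pa[1], pa[2]) == (pb[2], pb[1])

    def test_aai_equals_filter_then_average_reference(self, toy_proteomes):
        """Independent filter-then-average over align_pair hits."""
        a, b = toy_proteomes
        params = EXHAUSTIVE
        fwd = {}
        rev = {}
        for store, (qs, ss) in ((fwd, (a, b)), (rev, (b, a))):
            for q in qs.proteins:
                cands = []
                for s in ss.proteins:
                    hit = align_pair(q, s, params)
                    if hit is not None and hit.e_value <= params.aai_max_evalue:
                        cands.append(hit)
                best = None
                for h in sorted(cands, key=lambda h: h.subject_id):
                    if best is None or h.bit_score > best.bit_score:
                        best = h
                if best is not None:
                    store[q.id] = best
        idents = []
        for x, hx in fwd.items():
            hy = rev.get(hx.subject_id)
            if hy is not None and hy.subject_id == x:
                if all(h.identity >= params.aai_min_identity
                       and h.query_coverage >= params.aai_min_coverage
                       and h.e_value <= params.aai_max_evalue for h in (hx, hy)):
                    idents.append(0.5 * (hx.identity + hy.identity))
        expect = sum(idents) / len(idents)
        got, n_rbh = aai(a, b, params)
        assert got == pytest.approx(expect, abs=1e-12)
        assert n_rbh == len(idents)

    def test_pocp_equals_per_hit_counting_reference(self, toy_proteomes):
        a, b = toy_proteomes
        params = EXHAUSTIVE

        def conserved(qs, ss):
            n = 0
            for q in qs.proteins:
                for s in ss.proteins:
                    hit = align_pair(q, s, params)
                    if (hit is not None and hit.e_value < params.pocp_max_evalue
                            and hit.identity > params.pocp_min_identity
                            and hit.query_coverage > params.pocp_min_coverage):
                        n += 1
                        break
            return n

        c1, c2 = conserved(a, b), conserved(b, a)
        expect = 100.0 * (c1 + c2) / (a.n_proteins + b.n_proteins)
        got, gc1, gc2, t1, t2 = pocp(a, b, params)
        assert (gc1, gc2) == (c1, c2)
        assert got == pytest.approx(expect, abs=1e-12)

    def test_pocp_worked_case_is_exactly_60(self):
        """C = (3, 3), T = (4, 6) -> 100 x 6/10 = 60.0 exactly."""
        rng = random.Random(13)
        shared = [random_protein(rng, 60) for _ in range(3)]
        a = Proteome("a", [_rec(f"a{i}", s) for i, s in enumerate(shared)]
                     + [_rec("a3", random_protein(rng, 60))])
        b = Proteome("b", [_rec(f"b{i}", mutate(s, 3, rng))
                           for i, s in enumerate(shared)]
                     + [_rec(f"b{j}", random_protein(rng, 60))
                        for j in range(3, 6)])
        value, c1, c2, t1, t2 = pocp(a, b, EXHAUSTIVE)
        assert (c1, c2, t1, t2) == (3, 3, 4, 6)
        assert value == 60.0

    def test_prefilter_matches_exhaustive_on_related_proteomes(self, toy_proteomes):
        a, b = toy_proteomes
        assert pair_metrics(a, b, AlignParams()) == pair_metrics(a, b, EXHAUSTIVE)

    def test_monotone_degradation_with_divergence(self):
        """More planted substitutions never increases mean AAI."""
        rng = random.Random(14)
        fams = [random_protein(rng, 80) for _ in range(25)]
        a = Proteome("a", [_rec(f"a{i}", s) for i, s in enumerate(fams)])
        means = []
        for subs in (4, 12, 24):
            b = Proteome("b", [_rec(f"b{i}", mutate(s, subs, rng))
                               for i, s in enumerate(fams)])
            means.append(aai(a, b, EXHAUSTIVE)[0])
        assert means[0] >= means[1] - 1.0
        assert means[1] >= means[2] - 1.0
        assert means[0] > means[2]


class TestMarkerAAI:
    def _proteomes_with_markers(self, n_markers, subs_per_marker, seed=15):
        rng = random.Random(seed)
        markers = {f"m{k:03d}": random_protein(rng, 60) for k in range(n_markers)}
        a_prots, b_prots, map_a, map_b = [], [], {}, {}
        for name, seq in markers.items():
            a_prots.append(_rec(f"A_{name}", seq))
            b_prots.append(_rec(f"B_{name}", mutate(seq, subs_per_marker, rng)))
            map_a[name] = f"A_{name}"
            map_b[name] = f"B_{name}"
        return (Proteome("ga", a_prots), Proteome("gb", b_prots),
                {"ga": map_a, "gb": map_b})

    def test_identical_marker_sets_give_100(self):
        a, b, mm = self._proteomes_with_markers(5, 0)
        value, n = marker_aai(a, b, mm)
        assert value == 100.0 and n == 5

    def test_mean_over_shared_markers(self):
        rng = random.Random(16)
        s1, s2 = random_protein(rng, 50), random_protein(rng, 50)
        a = Proteome("ga", [_rec("a1", s1), _rec("a2", s2)])
        b = Proteome("gb", [_rec("b1", mutate(s1, 20, rng)),
                            _rec("b2", mutate(s2, 10, rng))])
        mm = {"ga": {"m1": "a1", "m2": "a2"}, "gb": {"m1": "b1", "m2": "b2"}}
        value, n = marker_aai(a, b, mm)
        i1 = 100.0 * 30 / 50
        i2 = 100.0 * 40 / 50
        assert n == 2
        assert value == pytest.approx((i1 + i2) / 2, abs=1e-9)

    def test_no_shared_markers_flagged(self):
        a, b, mm = self._proteomes_with_markers(3, 0)
        mm["gb"] = {}
        assert marker_aai(a, b, mm) == (None, 0)

    def test_recovers_planted_divergence(self):
        """128 markers, 9/60 substitutions each -> mean ~ 85 +- 0.5."""
        a, b, mm = self._proteomes_with_markers(128, 9, seed=17)
        value, n = marker_aai(a, b, mm)
        assert n == 128
        assert value == pytest.approx(85.0, abs=0.5)
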