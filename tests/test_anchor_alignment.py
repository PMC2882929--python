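"""Aligner tests: identity/strand behaviour, a quadratic-DP rescoring oracle,
and an exhaustive chaining oracle."""

import itertools

import numpy as np
import pytest

from polysynt.anchor_alignment import (
    AlignParams,
    AnchorHit,
    bit_score,
    chain_anchors,
    revcomp,
    seed_extend_align,
)
from polysynt.io_formats import SeqRecord, SeqRecordSet


def _rand_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _diverge(seq, rng, sub_rate=0.03, indels=2, indel_max=12):
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < sub_rate)[0]:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    for _ in range(indels):
        pos = int(rng.integers(50, len(out) - 50))
        ln = int(rng.integers(1, indel_max))
        if rng.random() < 0.5:
            del out[pos: pos + ln]
        else:
            out[pos:pos] = list(_rand_dna(rng, ln))
    return "".join(out)


def smith_waterman(a, b, match=1, mismatch=-2, gap_open=-5, gap_extend=-2):
    """Affine-gap local alignment score by full quadratic DP (oracle).

    Gap of length L costs gap_open + L * gap_extend, matching the package's
    scoring convention.
    """
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    F = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    first = gap_open + gap_extend
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + first, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + first, F[i - 1, j] + gap_extend)
            s = match if ai == b[j - 1] else mismatch
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
    return H.max()


def test_identity_slice_yields_single_full_hit(rng):
    tpl = _rand_dna(rng, 50_000)
    tset = SeqRecordSet([SeqRecord("chr1", tpl)])
    hits = seed_extend_align(SeqRecordSet([SeqRecord("q", tpl[20_000:30_000])]), tset)
    assert len(hits) == 1
    h = hits[0]
    assert (h.q_start, h.q_end) == (0, 10_000)
    assert (h.t_start, h.t_end) == (20_000, 30_000)
    assert h.strand == "+" and h.identity == 1.0 and h.raw_score == 10_000


def test_reverse_complement_query_maps_to_same_interval(rng):
    tpl = _rand_dna(rng, 30_000)
    tset = SeqRecordSet([SeqRecord("chr1", tpl)])
    q = revcomp(tpl[5_000:7_000])
    hits = seed_extend_align(SeqRecordSet([SeqRecord("q", q)]), tset)
    assert len(hits) == 1
    h = hits[0]
    assert (h.t_start, h.t_end) == (5_000, 7_000) and h.strand == "-"
    assert h.identity == 1.0


def test_alignment_symmetric_under_global_reverse_complement(rng):
    tpl = _rand_dna(rng, 20_000)
    q = _diverge(tpl[4_000:9_000], rng)
    fwd = seed_extend_align(
        SeqRecordSet([SeqRecord("q", q)]), SeqRecordSet([SeqRecord("t", tpl)])
    )
    rev = seed_extend_align(
        SeqRecordSet([SeqRecord("q", revcomp(q))]),
        SeqRecordSet([SeqRecord("t", revcomp(tpl))]),
    )
    def as_set(hits, qlen, tlen, reflect):
        out = set()
        for h in hits:
            if reflect:
                out.add(
                    (qlen - h.q_end, qlen - h.q_start, tlen - h.t_end,
                     tlen - h.t_start, h.strand, h.raw_score)
                )
            else:
                out.add((h.q_start, h.q_end, h.t_start, h.t_end, h.strand, h.raw_score))
        return out

    assert as_set(fwd, len(q), len(tpl), False) == as_set(rev, len(q), len(tpl), True)


def test_raw_scores_match_quadratic_dp_oracle(rng):
    """Each reported hit's raw score equals the SW optimum of its interval pair."""
    params = AlignParams(min_bit=100.0)
    for _ in range(6):
        tpl = _rand_dna(rng, 2_000)
        q = _diverge(tpl[200:1_800], rng, sub_rate=0.04, indels=2, indel_max=10)
        hits = seed_extend_align(
            SeqRecordSet([SeqRecord("q", q)]),
            SeqRecordSet([SeqRecord("t", tpl)]),
            params,
        )
        assert hits, "no hit found on diverged copy"
        for h in hits:
            sub_q = q[h.q_start: h.q_end]
            if h.strand == "-":
                sub_q = revcomp(sub_q)
            oracle = smith_waterman(sub_q, tpl[h.t_start: h.t_end])
            assert h.raw_score == pytest.approx(oracle, abs=1e-6)


def test_bit_score_formula_and_min_bit_monotonicity(rng):
    params = AlignParams()
    assert bit_score(200, params) == pytest.approx(
        (params.lam * 200 - np.log(params.K)) / np.log(2)
    )
    tpl = _rand_dna(rng, 20_000)
    q = _diverge(tpl[2_000:12_000], rng)
    qset = SeqRecordSet([SeqRecord("q", q)])
    tset = SeqRecordSet([SeqRecord("t", tpl)])
    lo = seed_extend_align(qset, tset, AlignParams(min_bit=50.0))
    hi = seed_extend_align(qset, tset, AlignParams(min_bit=400.0))
    key = lambda h: (h.q_start, h.q_end, h.t_start, h.t_end, h.strand)
    assert {key(h) for h in hi} <= {key(h) for h in lo}


def test_short_query_warns_and_returns_empty(rng):
    tset = SeqRecordSet([SeqRecord("t", _rand_dna(rng, 1000))])
    with pytest.warns(UserWarning, match="shorter than seed_k"):
        hits = seed_extend_align(SeqRecordSet([SeqRecord("q", "ACGTACGT")]), tset)
    assert hits == []


def test_masked_regions_are_not_seeded(rng):
    tpl = _rand_dna(rng, 6_000)
    masked_tpl = tpl[:2_000] + tpl[2_000:4_000].lower() + tpl[4_000:]
    q = tpl[2_500:3_500]  # lies entirely in the masked region
    hits = seed_extend_align(
        SeqRecordSet([SeqRecord("q", q)]),
        SeqRecordSet([SeqRecord("t", masked_tpl)]),
        AlignParams(min_bit=50.0),
    )
    assert hits == []


# ---------------------------------------------------------------------------
# chaining


def _hit(q0, q1, t0, t1, strand="+", bits=10.0):
    return AnchorHit("q", q0, q1, "chr", t0, t1, strand, bits, bits, 1.0)


def test_collinear_hits_form_single_chain():
    hits = [_hit(0, 100, 0, 100), _hit(200, 300, 150, 250), _hit(400, 500, 400, 500)]
    res = chain_anchors(hits)
    assert res.chain == sorted(hits, key=lambda h: h.t_start)
    assert res.off_chain == []


def test_inverted_hit_is_excluded_from_chain():
    inv = _hit(200, 300, 150, 250, strand="-")
    hits = [_hit(0, 100, 0, 100), inv, _hit(400, 500, 400, 500)]
    res = chain_anchors(hits)
    assert inv in res.off_chain and inv not in res.chain
    assert len(res.chain) == 2


def _exhaustive_best_chain(hits, max_gap):
    """Best collinear subset weight by brute force over all subsets."""
    best = 0.0
    for r in range(1, len(hits) + 1):
        for combo in itertools.combinations(hits, r):
            if len({(h.template_chrom, h.strand) for h in combo}) != 1:
                continue
            strand = combo[0].strand
            ordered = sorted(combo, key=lambda h: h.t_start)
            ok = True
            for a, b in zip(ordered, ordered[1:]):
                qa = (a.q_start, a.q_end) if strand == "+" else (-a.q_end, -a.q_start)
                qb = (b.q_start, b.q_end) if strand == "+" else (-b.q_end, -b.q_start)
                if a.t_end > b.t_start + 50 or qa[1] > qb[0] + 50:
                    ok = False
                    break
                if b.t_start - a.t_end > max_gap or qb[0] - qa[1] > max_gap:
                    ok = False
                    break
            if ok:
                best = max(best, sum(h.bit_score for h in combo))
    return best


def test_chain_weight_matches_exhaustive_oracle(rng):
    for _ in range(15):
        n = int(rng.integers(4, 11))
        hits = []
        for _i in range(n):
            q0 = int(rng.integers(0, 5_000))
            t0 = int(rng.integers(0, 5_000))
            ln = int(rng.integers(50, 400))
            strand = "+" if rng.random() < 0.8 else "-"
            hits.append(_hit(q0, q0 + ln, t0, t0 + ln, strand, float(rng.integers(1, 30))))
        res = chain_anchors(hits, max_gap=3_000)
        assert res.weight == pytest.approx(_exhaustive_best_chain(hits, 3_000))


def test_chain_invariant_to_hit_order(rng):
    hits = [
        _hit(0, 100, 0, 100, bits=5),
        _hit(150, 260, 140, 250, bits=7),
        _hit(500, 700, 480, 680, bits=3),
        _hit(90, 600, 1500, 2010, bits=6),
    ]
    base = chain_anchors(hits)
    for perm in itertools.permutations(hits):
        res = chain_anchors(list(perm))
        assert res.weight == base.weight
        assert sorted(h.t_start for h in res.chain) == sorted(
            h.t_start for h in base.chain
        )
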