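"""NG86 and molecular-clock tests, checked against independent oracles."""

import itertools
import math
import warnings

import numpy as np
import pytest
from Bio.Data import CodonTable

from polysynt.kaks_divergence import (
    AlignmentRejected,
    CodonAlignment,
    DivergenceEstimate,
    SaturationError,
    align_codons,
    estimate_divergence,
    kaks_pair,
    lower_median,
    ng86,
    translate,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_TABLE.stop_codons)
_NON_STOP = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
]


def _aa(codon):
    return "*" if codon in _STOPS else _TABLE.forward_table[codon]


def oracle_sites(codon):
    """Per-codon synonymous site count by direct enumeration."""
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_diffs(c1, c2):
    """Pathway-averaged (syn, nonsyn) differences by explicit enumeration."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    paths = []
    for perm in itertools.permutations(pos):
        cur, steps, blocked = c1, [], False
        for p in perm:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in _STOPS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [s for bl, s in paths if not bl] or [s for _, s in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if a not in _STOPS and b not in _STOPS and _aa(a) == _aa(b):
                syn += 1
            else:
                nonsyn += 1
    return syn / len(usable), nonsyn / len(usable)


def oracle_ng86(codons_a, codons_b):
    S = sum(oracle_sites(a) + oracle_sites(b) for a, b in zip(codons_a, codons_b)) / 2
    N = 3 * len(codons_a) - S
    Sd = Nd = 0.0
    for a, b in zip(codons_a, codons_b):
        s, n = oracle_diffs(a, b)
        Sd += s
        Nd += n
    ks = -0.75 * math.log(1 - 4 / 3 * (Sd / S))
    ka = -0.75 * math.log(1 - 4 / 3 * (Nd / N))
    return ks, ka, S, N, Sd, Nd


def _random_pair(rng, n_codons=40, n_subs=12):
    cods = [_NON_STOP[i] for i in rng.integers(0, len(_NON_STOP), n_codons)]
    a = "".join(cods)
    b = list(a)
    for i in rng.choice(len(b), size=n_subs, replace=False):
        b[i] = "ACGT"[rng.integers(0, 4)]
    # keep the mutant free of internal stops so the pair stays a valid CDS
    for j in range(0, len(b), 3):
        if "".join(b[j: j + 3]) in _STOPS:
            b[j: j + 3] = list(a[j: j + 3])
    return a, "".join(b)


def test_identical_sequences_have_zero_distance():
    r = kaks_pair("ATGGCTAAGGCT" * 15, "ATGGCTAAGGCT" * 15, check_reliability=False)
    assert r.Ks == 0.0 and r.Ka == 0.0
    assert r.S + r.N == pytest.approx(3 * 60)


def test_ng86_is_symmetric(rng):
    for _ in range(20):
        a, b = _random_pair(rng)
        r1 = kaks_pair(a, b, check_reliability=False)
        r2 = kaks_pair(b, a, check_reliability=False)
        assert r1.Ks == pytest.approx(r2.Ks, abs=1e-12)
        assert r1.Ka == pytest.approx(r2.Ka, abs=1e-12)


def test_ng86_matches_exhaustive_pathway_oracle(rng):
    for _ in range(150):
        a, b = _random_pair(rng, n_codons=30, n_subs=10)
        codons_a = [a[i: i + 3] for i in range(0, len(a), 3)]
        codons_b = [b[i: i + 3] for i in range(0, len(b), 3)]
        r = ng86(CodonAlignment(codons_a, codons_b, [True] * len(codons_a)))
        ks, ka, S, N, Sd, Nd = oracle_ng86(codons_a, codons_b)
        assert r.Ks == pytest.approx(ks, abs=1e-9)
        assert r.Ka == pytest.approx(ka, abs=1e-9)
        assert r.S == pytest.approx(S, abs=1e-9)
        assert r.Sd == pytest.approx(Sd, abs=1e-9)
        # conservation invariants
        assert r.S + r.N == pytest.approx(3 * len(codons_a), abs=1e-9)
        total, _ = 0.0, None
        total = sum(sum(oracle_diffs(x, y)) for x, y in zip(codons_a, codons_b))
        assert r.Sd + r.Nd == pytest.approx(total, abs=1e-9)


def test_ng86_agrees_with_biopython_on_stop_free_pairs(rng):
    """Cross-check against Bio.codonalign where pathway conventions coincide.

    Biopython weights stop-passing pathways instead of excluding them, so the
    comparison uses pairs whose codon differences never pass through a stop.
    """
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    checked = 0
    for _ in range(40):
        a, b = _random_pair(rng, n_codons=50, n_subs=14)
        codons_a = [a[i: i + 3] for i in range(0, len(a), 3)]
        codons_b = [b[i: i + 3] for i in range(0, len(b), 3)]
        def passes_stop(ca, cb):
            pos = [i for i in range(3) if ca[i] != cb[i]]
            for perm in itertools.permutations(pos):
                cur = ca
                for p in perm:
                    cur = cur[:p] + cb[p] + cur[p + 1:]
                    if cur in _STOPS:
                        return True
            return False

        stop_free = not any(passes_stop(x, y) for x, y in zip(codons_a, codons_b))
        if not stop_free:
            continue
        checked += 1
        r = ng86(CodonAlignment(codons_a, codons_b, [True] * len(codons_a)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert r.Ks == pytest.approx(ds, abs=1e-6)
        assert r.Ka == pytest.approx(dn, abs=1e-6)
    assert checked >= 10


def test_saturation_raises():
    # force pS >= 3/4 by maximally divergent synonymous-ish junk
    a = "GGT" * 60
    b = "GGC" * 60  # every codon differs synonymously: Sd large, S small
    codons_a = [a[i: i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i: i + 3] for i in range(0, len(b), 3)]
    with pytest.raises(SaturationError):
        ng86(CodonAlignment(codons_a, codons_b, [True] * 60))


def test_align_codons_identical_counts_all_columns():
    cds = "ATGGCTAAGGCTGATCCT" * 12
    aln = align_codons(cds, cds)
    assert all(aln.counted)
    assert len(aln.codons_a) == len(cds) // 3


def test_align_codons_single_codon_deletion_keeps_frame():
    cds = "ATGGCTAAGGCTGATCCTGGT" * 9
    b = cds[:30] + cds[33:]  # remove one codon
    aln = align_codons(cds, b)
    gaps = [i for i, c in enumerate(aln.codons_b) if c == "---"]
    assert gaps == [10]
    assert "".join(c for c in aln.codons_b if c != "---") == b
    assert "".join(aln.codons_a) == cds


def test_align_codons_back_mapping_round_trips(rng):
    """Re-translating the codon alignment reproduces the protein alignment."""
    for _ in range(10):
        a, b = _random_pair(rng, n_codons=60, n_subs=10)
        # delete a codon from b to force a gap
        b = b[:18] + b[21:]
        aln = align_codons(a, b, check_reliability=False)
        assert "".join(c for c in aln.codons_a if c != "---") == a
        assert "".join(c for c in aln.codons_b if c != "---") == b
        for ca, cb, ok in zip(aln.codons_a, aln.codons_b, aln.counted):
            if ok:
                assert "-" not in ca and "-" not in cb


def test_align_codons_rejects_internal_stop():
    good = "ATGGCTAAGGCT" * 20
    bad = good[:30] + "TAA" + good[33:]
    with pytest.raises(AlignmentRejected, match="stop"):
        align_codons(good, bad)


@pytest.mark.parametrize(
    "ks,mya", [(0.10, 7.7), (0.53, 40.8), (0.58, 44.6), (0.0, 0.0)]
)
def test_clock_dating(ks, mya):
    assert estimate_divergence([ks]).time_mya == mya


def test_clock_linearity(rng):
    ks = list(rng.uniform(0.01, 0.5, size=9))
    base = estimate_divergence(ks)
    for c in (0.5, 2.0, 3.0):
        scaled = estimate_divergence([c * k for k in ks])
        assert scaled.time_years == pytest.approx(c * base.time_years, rel=1e-12)


def test_lower_median_convention():
    assert lower_median([0.4, 0.1, 0.3, 0.2]) == 0.2
    assert lower_median([0.3, 0.1, 0.2]) == 0.2


def test_estimate_divergence_empty_errors():
    with pytest.raises(ValueError):
        estimate_divergence([])
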