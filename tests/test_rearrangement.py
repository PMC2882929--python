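"""Rearrangement classification against constructed and simulated events."""

import numpy as np
import pytest

from polysynt.anchor_alignment import AlignParams, revcomp, seed_extend_align
from polysynt.io_formats import Feature, FeatureTable, SeqRecord, SeqRecordSet
from polysynt.rearrangement_synteny import (
    RearrangementEvent,
    classify_rearrangements,
    detect_tandem_duplications,
    summarize_events,
)


def _rand_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _classify(query_seq, template, **kw):
    hits = seed_extend_align(
        SeqRecordSet([SeqRecord("q", query_seq)]), template, AlignParams()
    )
    return classify_rearrangements(hits, **kw)


def test_forced_inversion(rng):
    tpl = _rand_dna(rng, 30_000)
    tset = SeqRecordSet([SeqRecord("chr1", tpl)])
    q = tpl[:14_000] + revcomp(tpl[14_000:14_600]) + tpl[14_600:]
    events = _classify(q, tset)
    assert [e.event_class for e in events] == ["inversion"]
    e = events[0]
    assert e.t_start == pytest.approx(14_000, abs=20)
    assert e.length == pytest.approx(600, abs=40)


def test_forced_translocation_from_other_chromosome(rng):
    tpl_a = _rand_dna(rng, 25_000)
    tpl_b = _rand_dna(rng, 25_000)
    tset = SeqRecordSet([SeqRecord("chrA", tpl_a), SeqRecord("chrB", tpl_b)])
    q = tpl_a[:10_000] + tpl_b[5_000:5_500] + tpl_a[10_000:20_000]
    events = _classify(q, tset)
    assert [e.event_class for e in events] == ["translocation"]
    assert events[0].template_chrom == "chrB"


def test_forced_query_duplication(rng):
    tpl = _rand_dna(rng, 30_000)
    tset = SeqRecordSet([SeqRecord("chr1", tpl)])
    q = tpl[:18_000] + tpl[9_000:9_700] + tpl[18_000:26_000]
    events = _classify(q, tset)
    assert [e.event_class for e in events] == ["duplication_query"]
    assert events[0].t_start == pytest.approx(9_000, abs=20)


def test_forced_template_duplication(rng):
    # template has two copies of a segment; the query has one
    seg = _rand_dna(rng, 700)
    tpl = _rand_dna(rng, 8_000) + seg + _rand_dna(rng, 6_000) + seg + _rand_dna(rng, 8_000)
    tset = SeqRecordSet([SeqRecord("chr1", tpl)])
    q = tpl[2_000: 8_000 + 700 + 3_000]  # covers first copy only
    events = _classify(q, tset)
    assert [e.event_class for e in events] == ["duplication_template"]
    assert events[0].t_start == pytest.approx(8_000 + 700 + 6_000, abs=20)


def test_empty_hit_list_gives_no_events():
    assert classify_rearrangements([]) == []


def test_classification_invariant_under_query_reverse_complement(small_sim):
    clone = small_sim.clones[2]
    fwd = _classify(clone.seq, small_sim.masked)
    rev = _classify(revcomp(clone.seq.upper()), small_sim.masked)
    count = lambda evs: sorted((e.event_class, e.t_start) for e in evs)
    assert count(fwd) == count(rev)


def test_events_partition_off_chain_evidence(small_sim):
    from polysynt.anchor_alignment import chain_anchors

    clone = small_sim.clones[0]
    hits = seed_extend_align(
        SeqRecordSet([SeqRecord("q", clone.seq)]), small_sim.masked, AlignParams()
    )
    events = _classify(clone.seq, small_sim.masked)
    frame = chain_anchors(hits, 20_000)
    off_bp = sum(h.q_span() for h in frame.off_chain)
    aligned_bp = sum(h.q_span() for h in hits)
    assert sum(e.length for e in events) <= aligned_bp
    # every event length is backed by off-chain aligned bp
    assert sum(min(e.q_end - e.q_start, e.length) for e in events) <= off_bp + len(events) * 50


def _ev(cls, length):
    return RearrangementEvent(cls, "q", 0, length, "chr1", 0, length, length, 300.0)


def test_summary_means_follow_event_table_arithmetic():
    events = [_ev("duplication_query", 467)] * 25 + [_ev("duplication_query", 475)]
    table = summarize_events(events).table
    row = table[table["event_class"] == "duplication_query"].iloc[0]
    assert (row["total_bp"], row["n_events"], row["mean_bp"]) == (12_150, 26, 467)
    # single event: mean equals its length
    single = summarize_events([_ev("inversion", 842)]).table
    assert single[single["event_class"] == "inversion"].iloc[0]["mean_bp"] == 842
    # zero-event classes still reported
    assert (single["n_events"] == 0).sum() == 4


def test_summary_grand_total():
    spec = {
        "translocation": (1_925, 7),
        "inverted_translocation": (1_566, 4),
        "inversion": (842, 3),
        "duplication_query": (12_150, 26),
        "duplication_template": (4_595, 14),
    }
    events = []
    for cls, (total, n) in spec.items():
        lengths = [total // n] * n
        lengths[-1] += total - sum(lengths)
        events += [_ev(cls, ln) for ln in lengths]
    table = summarize_events(events).table
    grand = table[table["event_class"] == "Total"].iloc[0]
    assert (grand["total_bp"], grand["n_events"], grand["mean_bp"]) == (21_078, 54, 390)
    for cls, (total, n) in spec.items():
        row = table[table["event_class"] == cls].iloc[0]
        assert row["mean_bp"] == round(total / n)


def _gene(gid, seq_id, start, end, strand="+"):
    return Feature(seq_id, "t", "gene", start, end, strand, (("ID", gid),))


def test_tandem_triplet_versus_single_copy():
    genes_t = FeatureTable(
        [_gene("t1", "chr7", 1_000, 2_000), _gene("t2", "chr7", 3_000, 4_000),
         _gene("t3", "chr7", 5_000, 6_000)]
    )
    genes_q = FeatureTable([_gene("q1", "bac1", 500, 1_500)])
    orthologs = [("q1", "t1"), ("q1", "t2"), ("q1", "t3")]
    df = detect_tandem_duplications(genes_q, genes_t, orthologs)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row["copies_query"], row["copies_template"]) == (1, 3)


def test_equal_single_copies_not_reported():
    genes_t = FeatureTable([_gene("t1", "chr1", 100, 500)])
    genes_q = FeatureTable([_gene("q1", "bac", 100, 500)])
    assert len(detect_tandem_duplications(genes_q, genes_t, [("q1", "t1")])) == 0


def test_dispersed_copies_not_called_tandem():
    genes_t = FeatureTable(
        [_gene("t1", "chr1", 1_000, 2_000), _gene("t2", "chr2", 1_000, 2_000)]
    )
    genes_q = FeatureTable([_gene("q1", "bac", 100, 900)])
    df = detect_tandem_duplications(
        genes_q, genes_t, [("q1", "t1"), ("q1", "t2")], max_tandem_gap=20_000
    )
    assert len(df) == 0


def test_planted_tandem_arrays_recovered(rng):
    rows_t, rows_q, orthologs = [], [], []
    expected = []
    pos_t = pos_q = 0
    for fam in range(6):
        n_t = int(rng.integers(1, 4))
        n_q = int(rng.integers(1, 4))
        t_ids, q_ids = [], []
        for i in range(n_t):
            gid = f"t{fam}_{i}"
            rows_t.append(_gene(gid, "chrT", pos_t, pos_t + 500))
            pos_t += 1_000
            t_ids.append(gid)
        pos_t += 30_000
        for i in range(n_q):
            gid = f"q{fam}_{i}"
            rows_q.append(_gene(gid, "chrQ", pos_q, pos_q + 500))
            pos_q += 1_000
            q_ids.append(gid)
        pos_q += 30_000
        orthologs += [(q, t) for q in q_ids for t in t_ids]
        if n_t != n_q:
            expected.append((n_q, n_t))
    df = detect_tandem_duplications(FeatureTable(rows_q), FeatureTable(rows_t), orthologs)
    got = sorted(zip(df["copies_query"], df["copies_template"]))
    assert got == sorted(expected)
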