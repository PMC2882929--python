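"""Generator contracts: determinism, feasibility checks, calibration,
distributional properties and bookkeeping conservation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from polysynt.pool_deconvolution import Grid
from polysynt.synthetic_data import (
    ConfigError,
    SimConfig,
    fragment_clone,
    shear_and_pool,
    simulate_ortholog_pairs,
    simulate_polyploid_clones,
    simulate_probe_table,
    simulate_template,
    _pairwise_ks,
)


def _tiny_cfg(**kw):
    base = dict(
        n_chromosomes=2,
        chrom_length=60_000,
        insert_size_range=(15_000, 20_000),
        grid=(1, 2),
        coverage=4.0,
        read_length=300,
        gene_density=1 / 5_000,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


def test_same_seed_gives_byte_identical_outputs():
    cfg = _tiny_cfg()
    a_seqs, a_feats, a_truth = simulate_template(cfg)
    b_seqs, b_feats, b_truth = simulate_template(cfg)
    assert [(r.id, r.seq) for r in a_seqs] == [(r.id, r.seq) for r in b_seqs]
    assert a_feats.features == b_feats.features
    ca = simulate_polyploid_clones(a_seqs, a_truth, cfg)
    cb = simulate_polyploid_clones(b_seqs, b_truth, cfg)
    assert [(c.clone_id, c.seq) for c in ca] == [(c.clone_id, c.seq) for c in cb]
    pa, ta = shear_and_pool(ca, cfg)
    pb, tb = shear_and_pool(cb, cfg)
    assert [(p.pool_id, p.reads) for p in pa] == [(p.pool_id, p.reads) for p in pb]
    assert ta == tb


def test_zero_repeats_config_yields_genes_only():
    cfg = _tiny_cfg(repeat_fraction_template=0.0, repeat_fraction_query=0.0)
    seqs, feats, truth = simulate_template(cfg)
    assert truth.repeats == []
    assert {f.type for f in feats} <= {"gene", "exon"}
    for g in truth.genes:
        protein = str(Seq(g.cds).translate())
        assert protein.endswith("*") and "*" not in protein[:-1]
        assert protein.startswith("M")
        # genomic exon concatenation reproduces the CDS
        chrom = seqs[g.chrom].seq
        assert "".join(chrom[s:e] for s, e in g.exons) == g.cds


def test_template_repeat_fraction_within_band():
    cfg = SimConfig(n_chromosomes=2, chrom_length=200_000, seed=11,
                    insert_size_range=(30_000, 40_000))
    seqs, _feats, truth = simulate_template(cfg)
    total = sum(len(r.seq) for r in seqs)
    masked = sum(r.end - r.start for r in truth.repeats)
    assert abs(masked / total - cfg.repeat_fraction_template) <= 0.03


def test_gene_count_follows_poisson_band():
    """Realized gene counts across seeds stay in the Poisson 99% band."""
    density, length, n_seeds = 1 / 5_000, 50_000, 100
    counts = []
    for seed in range(n_seeds):
        cfg = SimConfig(
            n_chromosomes=1, chrom_length=length, gene_density=density,
            repeat_fraction_template=0.0, repeat_fraction_query=0.0,
            insert_size_range=(10_000, 12_000), grid=(1, 1), seed=seed,
        )
        _s, _f, truth = simulate_template(cfg)
        counts.append(len(truth.genes))
    mean = length * density * n_seeds
    total = sum(counts)
    # 99% normal band for a Poisson sum
    assert abs(total - mean) <= 2.58 * np.sqrt(mean)


def test_infeasible_density_raises():
    with pytest.raises(ConfigError, match="infeasible"):
        simulate_template(_tiny_cfg(gene_density=1 / 700, repeat_fraction_template=0.5))


def test_identity_limit_clone_equals_template_interval():
    cfg = _tiny_cfg(
        target_ks=0.0,
        indel_rate=0.0,
        expansion_bias=0.0,
        clone_specific_gene_rate=0.0,
        repeat_fraction_query=0.0,
        rearrangement_spectrum={},
    )
    seqs, _f, truth = simulate_template(cfg)
    clones = simulate_polyploid_clones(seqs, truth, cfg)
    for c in clones:
        t = c.truth
        assert c.seq == seqs[t.chrom].seq[t.t_start: t.t_end]
        assert t.events == []


def test_realized_ks_close_to_target(small_sim):
    ks = [
        _pairwise_ks(t, q)
        for c in small_sim.clones
        for (_g, t, q) in c.truth.orthologs
    ]
    assert len(ks) >= 8
    assert abs(float(np.median(ks)) - 0.10) <= 0.02


def test_exon_identity_calibrated(small_sim):
    """Purifying selection keeps exon identity near 95% at Ks 0.10."""
    ident = []
    for c in small_sim.clones:
        for _g, cds_t, cds_q in c.truth.orthologs:
            same = sum(a == b for a, b in zip(cds_t, cds_q))
            ident.append(same / len(cds_t))
    mean_ident = 100 * float(np.mean(ident))
    assert abs(mean_ident - 95.2) <= 1.5


def test_event_bookkeeping_matches_truth(small_sim):
    for c in small_sim.clones:
        by_class = {}
        for e in c.truth.events:
            by_class[e.event_class] = by_class.get(e.event_class, 0) + 1
            assert e.length > 0
            assert e.t_start < e.t_end
    # sanity: the configured spectrum classes all appear somewhere
    seen = {e.event_class for c in small_sim.clones for e in c.truth.events}
    assert seen == set(small_sim.cfg.rearrangement_spectrum)


def test_nine_pools_for_twenty_clones():
    cfg = SimConfig(
        n_chromosomes=4, chrom_length=12_000, insert_size_range=(2_000, 3_000),
        grid=(4, 5), coverage=2.0, read_length=300, gene_density=1 / 4_000,
        repeat_fraction_template=0.0, repeat_fraction_query=0.0,
        rearrangement_spectrum={}, expansion_bias=0.0, indel_rate=0.0,
        clone_specific_gene_rate=0.0, seed=1,
    )
    seqs, _f, truth = simulate_template(cfg)
    clones = simulate_polyploid_clones(seqs, truth, cfg)
    assert len(clones) == 20
    pools, read_truth = shear_and_pool(clones, cfg)
    assert len(pools) == 9  # 4 row pools + 5 column pools
    # conservation: every simulated read is in exactly one pool
    ids = [rid for p in pools for rid, _ in p.reads]
    assert len(ids) == len(set(ids)) == len(read_truth)
    # realized per-clone coverage within 15% of nominal
    by_clone = {c.clone_id: 0 for c in clones}
    for p in pools:
        for rid, seq in p.reads:
            by_clone[read_truth[rid]] += len(seq)
    for c in clones:
        realized = by_clone[c.clone_id] / len(c.seq)
        assert realized == pytest.approx(cfg.coverage, rel=0.15)


def test_read_length_exceeding_insert_errors():
    cfg = _tiny_cfg(read_length=30_000)
    seqs, _f, truth = simulate_template(cfg)
    clones = simulate_polyploid_clones(seqs, truth, cfg)
    with pytest.raises(ConfigError, match="read_length"):
        shear_and_pool(clones, cfg)


def test_probe_table_requires_enough_probes(small_sim):
    with pytest.raises(ConfigError, match="n_probes"):
        simulate_probe_table(small_sim.seqs, small_sim.clones, 3, small_sim.cfg)


def test_planted_multicopy_probe_counts(small_sim):
    table, ptruth = simulate_probe_table(
        small_sim.seqs, small_sim.clones, 40, small_sim.cfg
    )
    # planted single-copy probes carry the expected homolog band (10-12)
    pc = table.polyploid_counts.groupby("probe_id").size()
    for clone_id, (pa, pb) in ptruth.pair_by_clone.items():
        assert 10 <= pc[pa] <= 12
        assert 10 <= pc[pb] <= 12


def test_fragment_clone_round_trips(small_sim, rng):
    clone = small_sim.clones[0]
    cs, truth = fragment_clone(clone, 5, rng)
    assert len(cs.contigs) == 5
    joined = {cid: (a, b, o) for cid, a, b, o in truth}
    total = sum(b - a for _c, (a, b, _o) in joined.items())
    assert total == len(clone.seq)


def test_ortholog_pair_generator_hits_target():
    pairs = simulate_ortholog_pairs(60, 0.10, seed=21)
    ks = [_pairwise_ks(a, b) for a, b in pairs]
    assert abs(float(np.median(ks)) - 0.10) <= 0.02
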