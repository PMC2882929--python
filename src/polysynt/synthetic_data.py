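"""Synthetic template genomes, diverged polyploid clones, pooled reads and
probe tables, with full ground truth for recovery testing.

The generator emulates the study design the pipeline targets: a diploid
"template" genome (multi-chromosome, ~1 gene / 10.1 kb, ~27.6% labelled
repeats) and large-insert clones (40-165 kb) sampled from a diverged
polyploid relative.  Clones are template intervals carrying

* substitutions calibrated by closed loop against the package's own NG86
  implementation so the realized synonymous divergence of embedded CDS
  matches ``target_ks`` (default 0.10); nonsynonymous changes are accepted
  with probability ``omega`` (purifying selection),
* small indels outside exons,
* implanted rearrangements following the per-class count/mean-length
  spectrum of the clone-table (translocations, inverted translocations,
  inversions, duplications in either genome),
* repeat turnover: template-repeat contraction in the clone (which makes
  the template look expanded over aligned regions) plus clone-specific
  repeat insertions, and a fraction of clone-specific genes.

Reads are sheared uniformly and split between the clone's row pool and
column pool on an (n_rows x n_cols) grid; probe tables contain planted
single-copy probes, multi-copy probes and close probe pairs.

Every entity is recorded in a truth object, and identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import Feature, FeatureTable, SeqRecord, SeqRecordSet
from .kaks_divergence import CodonAlignment, STOP_CODONS, _aa, ng86
from .pool_deconvolution import Grid, PooledReadSet
from .probe_selection import ProbeHitTable
from .repeats_ssr import REPEAT_FAMILIES, RepeatLibrary


class ConfigError(ValueError):
    """Jointly infeasible or invalid simulation parameters."""


# Table-style defaults: per-class (n_events, mean_length_bp) across the clone set.
DEFAULT_REARRANGEMENT_SPECTRUM = {
    "translocation": (7, 275),
    "inverted_translocation": (4, 392),
    "inversion": (3, 281),
    "duplication_query": (26, 467),
    "duplication_template": (14, 328),
}

# Template repeat family weights (fractions of repeat bp by family).
DEFAULT_FAMILY_WEIGHTS = {
    "SINE": 0.13,
    "LINE/L1-CIN4": 0.38,
    "LTR/Copia": 6.16,
    "LTR/Gypsy-DIRS1": 9.80,
    "DNA/hobo-Activator": 0.20,
    "DNA/Tc1-Pogo": 0.28,
    "DNA/En-Spm": 1.95,
    "DNA/MuDR": 0.23,
    "DNA/Tourist-Harbinger": 3.93,
    "Unclassified": 1.21,
}

_CONSENSUS_LENGTHS = {
    "SINE": 200,
    "LINE/L1-CIN4": 1500,
    "LTR/Copia": 1200,
    "LTR/Gypsy-DIRS1": 1200,
    "DNA/hobo-Activator": 600,
    "DNA/Tc1-Pogo": 700,
    "DNA/En-Spm": 900,
    "DNA/MuDR": 800,
    "DNA/Tourist-Harbinger": 400,
    "Unclassified": 500,
}


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length: int = 300_000
    gene_density: float = 1.0 / 10_100  # genes per bp
    repeat_fraction_template: float = 0.276
    repeat_fraction_query: float = 0.255
    target_ks: float = 0.10
    omega: float = 0.3  # acceptance probability of nonsynonymous substitutions
    indel_rate: float = 2e-4  # per non-exon bp
    indel_mean_len: float = 3.0
    rearrangement_spectrum: dict = field(
        default_factory=lambda: dict(DEFAULT_REARRANGEMENT_SPECTRUM)
    )
    min_event_length: int = 200
    expansion_bias: float = 207.0  # template-repeat bp contracted per clone kb
    clone_specific_gene_rate: float = 17.0 / 209.0
    insert_size_range: tuple[int, int] = (40_000, 165_000)
    read_length: int = 500
    coverage: float = 64.0
    grid: tuple[int, int] = (4, 5)
    n_clones: int | None = None  # default: one per grid cell
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("repeat_fraction_template", "repeat_fraction_query"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.coverage <= 0:
            raise ConfigError("coverage must be positive")
        n_clones = self.resolved_n_clones()
        if self.grid[0] * self.grid[1] < n_clones:
            raise ConfigError("grid smaller than the number of clones")
        if self.insert_size_range[0] > self.insert_size_range[1]:
            raise ConfigError("insert size range inverted")

    def resolved_n_clones(self) -> int:
        return self.n_clones if self.n_clones is not None else self.grid[0] * self.grid[1]


# ---------------------------------------------------------------------------
# truth records


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    exons: list[tuple[int, int]]  # genomic coordinates, ascending
    cds: str


@dataclass(frozen=True)
class RepeatCopy:
    chrom: str
    start: int
    end: int
    family: str


@dataclass(frozen=True)
class DupPair:
    chrom: str
    first: tuple[int, int]
    second: tuple[int, int]


@dataclass
class TemplateTruth:
    genes: list[GeneModel]
    repeats: list[RepeatCopy]
    dup_pairs: list[DupPair]
    library: RepeatLibrary

    def gene_features(self) -> FeatureTable:
        feats = []
        for g in self.genes:
            feats.append(
                Feature(g.chrom, "sim", "gene", g.start, g.end, "+", (("ID", g.gene_id),))
            )
            for i, (s, e) in enumerate(g.exons):
                feats.append(
                    Feature(
                        g.chrom, "sim", "exon", s, e, "+",
                        (("Parent", g.gene_id), ("exon_number", str(i + 1))),
                    )
                )
        return FeatureTable(feats).sorted()

    def repeat_features(self) -> FeatureTable:
        return FeatureTable(
            [
                Feature(r.chrom, "sim", "repeat", r.start, r.end, "+", (("family", r.family),))
                for r in self.repeats
            ]
        ).sorted()


@dataclass(frozen=True)
class ImplantedEvent:
    event_class: str
    clone_id: str
    template_chrom: str
    t_start: int  # template interval characterising the event (source/extra copy)
    t_end: int
    length: int


@dataclass
class CloneTruth:
    clone_id: str
    chrom: str
    t_start: int
    t_end: int
    p_sub: float
    events: list[ImplantedEvent] = field(default_factory=list)
    orthologs: list[tuple[str, str, str]] = field(default_factory=list)  # (gene_id, cds_template, cds_clone)
    gene_locations: dict[str, tuple[int, int]] = field(default_factory=dict)  # clone coords
    specific_genes: list[str] = field(default_factory=list)


@dataclass
class BacClone:
    clone_id: str
    seq: str
    truth: CloneTruth

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# sequence helpers

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
_RC = str.maketrans("ACGT", "TGCA")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(list("ACGT"), size=n).tobytes().decode() if False else "".join(
        np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
    )


def _rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _draw_base(old: str, rng: np.random.Generator) -> str:
    r = rng.random()
    if r < 0.5:  # transition:transversion 2:1
        return _TRANSITION[old]
    tv = _TRANSVERSIONS[old]
    return tv[0] if r < 0.75 else tv[1]


def _mutate_neutral(seq: str, p: float, rng: np.random.Generator,
                    protect: np.ndarray | None = None) -> str:
    """Uniform substitutions at per-base probability p, ts:tv 2:1."""
    if p <= 0 or not seq:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < p
    if protect is not None:
        hit &= ~protect
    idx = np.nonzero(hit)[0]
    for i in idx:
        if arr[i] in _TRANSITION:
            arr[i] = _draw_base(arr[i], rng)
    return "".join(arr)


def _mutate_cds(cds: str, p: float, omega: float, rng: np.random.Generator) -> str:
    """Codon-aware substitutions: synonymous accepted, nonsynonymous with
    probability omega, changes creating stop codons rejected."""
    if p <= 0:
        return cds
    arr = list(cds)
    idx = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in idx:
        old = arr[i]
        if old not in _TRANSITION:
            continue
        new = _draw_base(old, rng)
        c0 = 3 * (i // 3)
        codon_old = "".join(arr[c0: c0 + 3])
        k = i - c0
        codon_new = codon_old[:k] + new + codon_old[k + 1:]
        if codon_new in STOP_CODONS or codon_old in STOP_CODONS:
            continue
        if _aa(codon_new) == _aa(codon_old) or rng.random() < omega:
            arr[i] = new
    return "".join(arr)


def _pairwise_ks(cds_a: str, cds_b: str) -> float:
    """NG86 Ks for two equal-length in-frame CDS (no alignment needed)."""
    codons_a = [cds_a[i: i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i: i + 3] for i in range(0, len(cds_b), 3)]
    counted = [
        a not in STOP_CODONS and b not in STOP_CODONS
        for a, b in zip(codons_a, codons_b)
    ]
    return ng86(CodonAlignment(codons_a, codons_b, counted)).Ks


def calibrate_substitution_rate(
    cds_list: list[str],
    target_ks: float,
    omega: float,
    seed: int,
    tol: float = 0.002,
) -> float:
    """Closed-loop calibration of the per-base substitution probability.

    Binary search for the rate at which the median NG86 Ks of mutated
    copies of ``cds_list`` (measured by the package's own estimator)
    matches ``target_ks``.  The same child RNG stream is replayed at each
    trial rate so the realized Ks is monotone in the rate.
    """
    if target_ks <= 0:
        return 0.0

    def realized(p: float) -> float:
        rng = np.random.default_rng(seed)
        ks = []
        for cds in cds_list:
            mutated = _mutate_cds(cds, p, omega, rng)
            ks.append(_pairwise_ks(cds, mutated))
        return float(np.median(ks))

    lo, hi = 0.0, min(0.6, max(0.05, 4.0 * target_ks))
    while realized(hi) < target_ks and hi < 0.6:
        hi = min(0.6, hi * 1.5)
    for _ in range(40):
        mid = (lo + hi) / 2
        r = realized(mid)
        if abs(r - target_ks) < tol:
            return mid
        if r < target_ks:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


# ---------------------------------------------------------------------------
# template generation


def default_repeat_library(rng: np.random.Generator) -> RepeatLibrary:
    entries = []
    for fam in REPEAT_FAMILIES:
        n = _CONSENSUS_LENGTHS[fam]
        entries.append((f"cons_{fam.replace('/', '_')}", fam, _random_dna(rng, n)))
    return RepeatLibrary(entries)


def _make_gene(rng: np.random.Generator, gene_id: str) -> tuple[str, list[tuple[int, int]], str]:
    """Random multi-exon gene: returns (genomic seq, exon intervals, CDS)."""
    n_exons = int(rng.integers(1, 5))
    exon_lens = [3 * int(rng.integers(50, 160)) for _ in range(n_exons)]
    n_codons = sum(exon_lens) // 3
    codons = ["ATG"]
    non_stop = [c for c in _ALL_CODONS if c not in STOP_CODONS and c != "ATG"]
    body = rng.integers(0, len(non_stop), size=n_codons - 2)
    codons += [non_stop[i] for i in body]
    codons.append("TAA")
    cds = "".join(codons)
    parts = []
    exons = []
    pos = 0
    cds_pos = 0
    for i, elen in enumerate(exon_lens):
        exon_seq = cds[cds_pos: cds_pos + elen]
        cds_pos += elen
        parts.append(exon_seq)
        exons.append((pos, pos + elen))
        pos += elen
        if i < n_exons - 1:
            intron = "GT" + _random_dna(rng, int(rng.integers(80, 400))) + "AG"
            parts.append(intron)
            pos += len(intron)
    return "".join(parts), exons, cds


_ALL_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]


def simulate_template(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[SeqRecordSet, FeatureTable, TemplateTruth]:
    """Generate the diploid template genome with genes and labelled repeats."""
    rng = rng or np.random.default_rng(cfg.seed)
    library = default_repeat_library(rng)
    genes: list[GeneModel] = []
    repeats: list[RepeatCopy] = []
    dup_pairs: list[DupPair] = []
    records = []
    n_dup_pairs_total = cfg.rearrangement_spectrum.get("duplication_template", (0, 0))[0]
    gene_counter = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        L = cfg.chrom_length
        n_genes = int(rng.poisson(L * cfg.gene_density))
        gene_payloads = []
        for _ in range(n_genes):
            gene_counter += 1
            gene_payloads.append((_make_gene(rng, f"g{gene_counter:04d}"), gene_counter))
        gene_bp = sum(len(seq) for (seq, _x, _c), _n in gene_payloads)
        target_repeat_bp = int(cfg.repeat_fraction_template * L)
        if gene_bp + target_repeat_bp > 0.9 * L:
            raise ConfigError(
                "gene density and repeat fraction jointly infeasible for chrom_length"
            )
        free = L - gene_bp
        gaps = rng.multinomial(free, np.ones(n_genes + 1) / (n_genes + 1))
        parts = []
        pos = 0
        chrom_genes = []
        for gi, ((gseq, gexons, gcds), gnum) in enumerate(gene_payloads):
            gap_seq = _random_dna(rng, int(gaps[gi]))
            parts.append(gap_seq)
            pos += len(gap_seq)
            chrom_genes.append(
                GeneModel(
                    gene_id=f"g{gnum:04d}",
                    chrom=chrom,
                    start=pos,
                    end=pos + len(gseq),
                    exons=[(pos + s, pos + e) for s, e in gexons],
                    cds=gcds,
                )
            )
            parts.append(gseq)
            pos += len(gseq)
        parts.append(_random_dna(rng, int(gaps[n_genes])))
        seq = list("".join(parts))

        # occupied intervals: exons (with margin) are never overwritten
        occupied: list[tuple[int, int]] = []
        for g in chrom_genes:
            occupied.append((g.start - 50, g.end + 50))
        occupied.sort()

        def _free_slot(length: int, lo: int = 0, hi: int | None = None, tries: int = 300):
            hi = hi if hi is not None else L
            if hi - lo <= length:
                return None
            for _ in range(tries):
                s = int(rng.integers(lo, hi - length))
                e = s + length
                if all(e <= os or s >= oe for os, oe in occupied):
                    return s, e
            return None

        # dispersed near-duplicate segment pairs (template-side duplications)
        n_pairs_here = n_dup_pairs_total // cfg.n_chromosomes + (
            1 if ci < n_dup_pairs_total % cfg.n_chromosomes else 0
        )
        mean_len = cfg.rearrangement_spectrum.get("duplication_template", (0, 328))[1]
        for _ in range(n_pairs_here):
            seg_len = _event_length(rng, mean_len, cfg.min_event_length)
            slot1 = _free_slot(seg_len)
            if slot1 is None:
                continue
            occupied.append(slot1)
            occupied.sort()
            lo2 = max(0, slot1[0] - 15_000)
            hi2 = min(L, slot1[1] + 15_000)
            slot2 = _free_slot(seg_len, lo2, hi2)
            if slot2 is None:
                occupied.remove(slot1)
                occupied.sort()
                continue
            occupied.append(slot2)
            occupied.sort()
            content = _random_dna(rng, seg_len)
            content2 = _mutate_neutral(content, 0.02, rng)
            seq[slot1[0]: slot1[1]] = list(content)
            seq[slot2[0]: slot2[1]] = list(content2)
            pair = (
                DupPair(chrom, slot1, slot2)
                if slot1[0] < slot2[0]
                else DupPair(chrom, slot2, slot1)
            )
            dup_pairs.append(pair)

        # labelled repeat copies until the target fraction is reached
        repeat_bp = 0
        fams = list(DEFAULT_FAMILY_WEIGHTS)
        weights = np.array([DEFAULT_FAMILY_WEIGHTS[f] for f in fams])
        weights = weights / weights.sum()
        attempts = 0
        while repeat_bp < target_repeat_bp and attempts < 10_000:
            attempts += 1
            fam = fams[int(rng.choice(len(fams), p=weights))]
            cons = next(c for n, f, c in library.entries if f == fam)
            copy_len = int(rng.integers(max(120, len(cons) // 3), len(cons) + 1))
            start_in_cons = int(rng.integers(0, len(cons) - copy_len + 1))
            copy = _mutate_neutral(cons[start_in_cons: start_in_cons + copy_len], 0.03, rng)
            slot = _free_slot(copy_len)
            if slot is None:
                continue
            occupied.append(slot)
            occupied.sort()
            seq[slot[0]: slot[1]] = list(copy)
            repeats.append(RepeatCopy(chrom, slot[0], slot[1], fam))
            repeat_bp += copy_len
        genes.extend(chrom_genes)
        records.append(SeqRecord(id=chrom, seq="".join(seq)))
    truth = TemplateTruth(genes=genes, repeats=repeats, dup_pairs=dup_pairs, library=library)
    features = FeatureTable(
        truth.gene_features().features + truth.repeat_features().features
    ).sorted()
    return SeqRecordSet(records), features, truth


def _event_length(rng: np.random.Generator, mean: int, floor: int) -> int:
    """Shifted-geometric event length: floor + Geom(mean - floor), mean preserved."""
    if mean <= floor:
        return int(mean)
    excess = mean - floor
    return floor + int(rng.geometric(1.0 / excess)) - 1


# ---------------------------------------------------------------------------
# clone simulation


def simulate_polyploid_clones(
    template: SeqRecordSet,
    truth: TemplateTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[BacClone]:
    """Sample diverged clone inserts from the template with implanted events."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n_clones = cfg.resolved_n_clones()
    chrom_lengths = {r.id: len(r.seq) for r in template}
    if cfg.insert_size_range[0] > max(chrom_lengths.values()):
        raise ConfigError("insert_size_range exceeds chromosome length")
    # calibrate the substitution rate against the NG86 estimator
    sample_cds = [g.cds for g in truth.genes[:40]] or []
    p_sub = (
        calibrate_substitution_rate(sample_cds, cfg.target_ks, cfg.omega, cfg.seed + 99)
        if sample_cds
        else 0.0
    )
    # distribute the event spectrum round-robin over clones
    assignments: dict[int, list[str]] = {i: [] for i in range(n_clones)}
    slot = 0
    for cls, (count, _mean) in sorted(cfg.rearrangement_spectrum.items()):
        if cls == "duplication_template":
            continue  # realized through planted template pairs below
        for _ in range(count):
            assignments[slot % n_clones].append(cls)
            slot += 1
    # assign planted template dup pairs to clones (cycling chromosomes)
    pairs_by_chrom: dict[str, list[DupPair]] = {}
    for pair in truth.dup_pairs:
        pairs_by_chrom.setdefault(pair.chrom, []).append(pair)
    chroms = [r.id for r in template]
    clones = []
    pair_cursor: dict[str, int] = {c: 0 for c in chroms}
    for i in range(n_clones):
        clone_id = f"clone{i + 1:02d}"
        chrom = chroms[i % len(chroms)]
        L = chrom_lengths[chrom]
        insert_len = int(
            rng.integers(
                min(cfg.insert_size_range[0], L),
                min(cfg.insert_size_range[1], L) + 1,
            )
        )
        # centre the interval on an unused planted pair when one is available
        pair_list = pairs_by_chrom.get(chrom, [])
        anchor_pair = None
        if pair_cursor[chrom] < len(pair_list):
            cand = pair_list[pair_cursor[chrom]]
            if cand.second[1] - cand.first[0] < insert_len - 2000:
                anchor_pair = cand
                pair_cursor[chrom] += 1
        if anchor_pair is not None:
            span_lo = max(0, anchor_pair.second[1] + 1000 - insert_len)
            span_hi = min(L - insert_len, anchor_pair.first[0] - 1000)
            t0 = int(rng.integers(span_lo, max(span_lo + 1, span_hi + 1)))
            t0 = min(t0, L - insert_len)
        else:
            t0 = int(rng.integers(0, L - insert_len + 1))
        t1 = t0 + insert_len
        clone = _build_clone(
            clone_id, template[chrom].seq, chrom, t0, t1, truth, cfg,
            assignments[i], p_sub, rng,
        )
        clones.append(clone)
    return clones


def _sample_free(rng, lo, hi, length, occupied, tries=300):
    if hi - lo <= length:
        return None
    for _ in range(tries):
        s = int(rng.integers(lo, hi - length))
        e = s + length
        if all(e + 100 <= os or s - 100 >= oe for os, oe in occupied):
            return (s, e)
    return None


def _build_clone(
    clone_id: str,
    chrom_seq: str,
    chrom: str,
    t0: int,
    t1: int,
    truth: TemplateTruth,
    cfg: SimConfig,
    event_classes: list[str],
    p_sub: float,
    rng: np.random.Generator,
) -> BacClone:
    genes_in = [g for g in truth.genes if g.chrom == chrom and g.start >= t0 and g.end <= t1]
    repeats_in = [
        r for r in truth.repeats if r.chrom == chrom and r.start >= t0 and r.end <= t1
    ]
    pairs_in = [
        p
        for p in truth.dup_pairs
        if p.chrom == chrom and p.first[0] >= t0 and p.second[1] <= t1
    ]
    occupied: list[tuple[int, int]] = [(g.start - 50, g.end + 50) for g in genes_in]
    # events avoid template repeat territory: repeats are masked before
    # anchoring, so evidence inside them would be invisible downstream
    occupied += [(r.start, r.end) for r in repeats_in]
    for p in pairs_in:
        occupied.append(p.first)
        occupied.append(p.second)
    occupied.sort()

    ctruth = CloneTruth(clone_id=clone_id, chrom=chrom, t_start=t0, t_end=t1, p_sub=p_sub)
    deletions: list[tuple[int, int]] = []  # template sub-intervals absent from clone
    inversions: list[tuple[int, int]] = []
    insertions: list[tuple[int, str, str]] = []  # (breakpoint, content, kind)

    # template-side duplications: drop the second copy from the clone
    for p in pairs_in:
        deletions.append(p.second)
        ctruth.events.append(
            ImplantedEvent(
                "duplication_template", clone_id, chrom,
                p.second[0], p.second[1], p.second[1] - p.second[0],
            )
        )
    # pairs with exactly one copy inside the interval are template-side
    # duplications as well: one clone copy, two template copies
    for p in truth.dup_pairs:
        if p.chrom != chrom or p in pairs_in:
            continue
        for kept, extra in ((p.first, p.second), (p.second, p.first)):
            if t0 <= kept[0] and kept[1] <= t1 and (extra[1] <= t0 or extra[0] >= t1):
                occupied.append(kept)
                ctruth.events.append(
                    ImplantedEvent(
                        "duplication_template", clone_id, chrom,
                        extra[0], extra[1], extra[1] - extra[0],
                    )
                )
    occupied.sort()

    # repeat contraction (makes the template look expanded over aligned bp)
    contraction_target = cfg.expansion_bias * (t1 - t0) / 1000.0
    contracted = 0
    for r in sorted(repeats_in, key=lambda r: r.start):
        if contracted >= contraction_target:
            break
        if any(not (r.end <= s or r.start >= e) for s, e in deletions):
            continue
        deletions.append((r.start, r.end))
        contracted += r.end - r.start

    for cls in event_classes:
        mean = cfg.rearrangement_spectrum[cls][1]
        length = _event_length(rng, mean, cfg.min_event_length)
        if cls == "inversion":
            slot = _sample_free(rng, t0, t1, length, occupied + deletions + inversions)
            if slot is None:
                continue
            inversions.append(slot)
            occupied.append(slot)
            occupied.sort()
            ctruth.events.append(
                ImplantedEvent("inversion", clone_id, chrom, slot[0], slot[1], length)
            )
        elif cls in ("translocation", "inverted_translocation"):
            # source: a distant clean template interval
            exts = [(g.start, g.end) for g in truth.genes if g.chrom == chrom]
            exts += [(r.start, r.end) for r in truth.repeats if r.chrom == chrom]
            exts += [iv for p2 in truth.dup_pairs if p2.chrom == chrom
                     for iv in (p2.first, p2.second)]
            exts += [(t0 - 5000, t1 + 5000)]
            src = _sample_free(rng, 0, len(chrom_seq), length, sorted(exts))
            if src is None:
                continue
            content = chrom_seq[src[0]: src[1]]
            if cls == "inverted_translocation":
                content = _rc(content)
            content = _mutate_neutral(content, p_sub, rng)
            bp = _sample_breakpoint(rng, t0, t1, occupied + deletions + inversions)
            if bp is None:
                continue
            insertions.append((bp, content, cls))
            occupied.append((bp - 100, bp + 100))
            occupied.sort()
            ctruth.events.append(
                ImplantedEvent(cls, clone_id, chrom, src[0], src[1], length)
            )
        elif cls == "duplication_query":
            src = _sample_free(rng, t0, t1, length, occupied + deletions + inversions)
            if src is None:
                continue
            occupied.append(src)
            occupied.sort()
            content = _mutate_neutral(chrom_seq[src[0]: src[1]], p_sub, rng)
            bp = _sample_breakpoint(rng, t0, t1, occupied + deletions + inversions)
            if bp is None:
                continue
            insertions.append((bp, content, cls))
            occupied.append((bp - 100, bp + 100))
            occupied.sort()
            ctruth.events.append(
                ImplantedEvent("duplication_query", clone_id, chrom, src[0], src[1], length)
            )

    # clone-specific genes
    n_spec = int(rng.binomial(max(len(genes_in), 1), cfg.clone_specific_gene_rate))
    for si in range(n_spec):
        gseq, _exons, _cds = _make_gene(rng, f"{clone_id}_spec{si}")
        bp = _sample_breakpoint(rng, t0, t1, occupied + deletions + inversions)
        if bp is None:
            continue
        insertions.append((bp, gseq, "specific_gene"))
        occupied.append((bp - 100, bp + 100))
        occupied.sort()
        ctruth.specific_genes.append(f"{clone_id}_spec{si}")

    # clone-specific repeat insertions toward the query repeat fraction
    remaining_repeat = sum(
        r.end - r.start
        for r in repeats_in
        if not any(not (r.end <= s or r.start >= e) for s, e in deletions)
    )
    clone_len_est = (t1 - t0) - sum(e - s for s, e in deletions)
    target_q_repeat = cfg.repeat_fraction_query * clone_len_est
    lib = truth.library
    guard = 0
    while remaining_repeat < target_q_repeat and guard < 500 and lib.entries:
        guard += 1
        name, fam, cons = lib.entries[int(rng.integers(0, len(lib.entries)))]
        copy_len = int(rng.integers(max(120, len(cons) // 3), len(cons) + 1))
        copy = _mutate_neutral(cons[:copy_len], 0.03, rng)
        bp = _sample_breakpoint(rng, t0, t1, occupied + deletions + inversions)
        if bp is None:
            break
        insertions.append((bp, copy, "repeat"))
        occupied.append((bp - 100, bp + 100))
        occupied.sort()
        remaining_repeat += copy_len

    # ---- assemble the clone sequence ----
    cut_points = sorted(
        set([t0, t1] + [x for s, e in deletions + inversions for x in (s, e)])
    )
    del_set = sorted(deletions)
    inv_set = sorted(inversions)
    ins_by_bp: dict[int, list[tuple[str, str]]] = {}
    for bp, content, kind in insertions:
        ins_by_bp.setdefault(bp, []).append((content, kind))

    pieces: list[dict] = []  # {'kind','seq','t_start','t_end'} template pieces track coords
    for a, b in zip(cut_points, cut_points[1:]):
        if any(s <= a and b <= e for s, e in del_set):
            continue
        if any(s <= a and b <= e for s, e in inv_set):
            pieces.append({"kind": "inversion", "t_start": a, "t_end": b,
                           "seq": _mutate_neutral(_rc(chrom_seq[a:b]), p_sub, rng)})
        else:
            pieces.append({"kind": "syntenic", "t_start": a, "t_end": b, "seq": None})
    # interleave insertions at their breakpoints
    final_items: list[dict] = []
    for piece in pieces:
        a, b = piece["t_start"], piece["t_end"]
        bps = sorted(bp for bp in ins_by_bp if a < bp <= b)
        if piece["kind"] != "syntenic" or not bps:
            final_items.append(piece)
            for bp in bps:
                for content, kind in ins_by_bp[bp]:
                    final_items.append({"kind": kind, "seq": content})
            continue
        prev = a
        for bp in bps:
            if bp > prev:
                final_items.append({"kind": "syntenic", "t_start": prev, "t_end": bp, "seq": None})
            for content, kind in ins_by_bp[bp]:
                final_items.append({"kind": kind, "seq": content})
            prev = bp
        if prev < b:
            final_items.append({"kind": "syntenic", "t_start": prev, "t_end": b, "seq": None})

    # mutate syntenic pieces (codon-aware in exons, neutral elsewhere), add indels
    clone_parts: list[str] = []
    pos_in_clone = 0
    exon_by_gene = {g.gene_id: g for g in genes_in}
    for item in final_items:
        if item["kind"] != "syntenic":
            clone_parts.append(item["seq"])
            pos_in_clone += len(item["seq"])
            continue
        a, b = item["t_start"], item["t_end"]
        seg = list(chrom_seq[a:b])
        exon_mask = np.zeros(b - a, dtype=bool)
        inner_genes = [g for g in genes_in if g.start >= a and g.end <= b]
        for g in inner_genes:
            for es, ee in g.exons:
                exon_mask[es - a: ee - a] = True
        # codon-aware CDS mutation written back through exon coordinates
        for g in inner_genes:
            mutated = _mutate_cds(g.cds, p_sub, cfg.omega, rng)
            cpos = 0
            for es, ee in g.exons:
                seg[es - a: ee - a] = list(mutated[cpos: cpos + (ee - es)])
                cpos += ee - es
            ctruth.orthologs.append((g.gene_id, g.cds, mutated))
        seg_str = _mutate_neutral("".join(seg), p_sub, rng, protect=exon_mask)
        # indels outside exons, applied right-to-left, offsets tracked
        seg_list = list(seg_str)
        free_pos = np.nonzero(~exon_mask)[0]
        hit = free_pos[rng.random(len(free_pos)) < cfg.indel_rate]
        indels = []  # (pos_in_seg, delta)
        for ip in sorted((int(x) for x in hit), reverse=True):
            ilen = int(rng.geometric(1.0 / cfg.indel_mean_len))
            if rng.random() < 0.5:
                ilen = min(ilen, b - a - ip)
                if exon_mask[ip: ip + ilen].any():
                    continue
                del seg_list[ip: ip + ilen]
                indels.append((ip, -ilen))
            else:
                seg_list[ip:ip] = list(_random_dna(rng, ilen))
                indels.append((ip, ilen))
        indels.sort()
        ind_pos = np.array([p for p, _ in indels], dtype=np.int64)
        ind_cum = np.cumsum([d for _, d in indels]) if indels else np.array([])

        def map_t(tp: int) -> int:
            off = int(ind_cum[np.searchsorted(ind_pos, tp - a, side="right") - 1]) if len(ind_pos) and tp - a >= ind_pos[0] else 0
            return pos_in_clone + (tp - a) + off

        for g in inner_genes:
            ctruth.gene_locations[g.gene_id] = (map_t(g.start), map_t(g.end))
        clone_parts.append("".join(seg_list))
        pos_in_clone += len(seg_list)
    return BacClone(clone_id=clone_id, seq="".join(clone_parts), truth=ctruth)


def _sample_breakpoint(rng, lo, hi, occupied, tries=300):
    for _ in range(tries):
        bp = int(rng.integers(lo + 500, hi - 500))
        if all(bp + 100 <= s or bp - 100 >= e for s, e in occupied):
            return bp
    return None


# ---------------------------------------------------------------------------
# pooled shotgun reads


def shear_and_pool(
    clones: list[BacClone],
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PooledReadSet], dict[str, str]]:
    """Shear clones into reads split between their row and column pools.

    Returns the pools (rows then columns) and the read -> clone truth map.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    grid = Grid(*cfg.grid)
    pools = [
        PooledReadSet(pool_id=f"row{r}", axis="row", index=r) for r in range(grid.n_rows)
    ] + [
        PooledReadSet(pool_id=f"col{c}", axis="col", index=c) for c in range(grid.n_cols)
    ]
    truth: dict[str, str] = {}
    counter = 0
    for i, clone in enumerate(clones):
        if cfg.read_length > len(clone.seq):
            raise ConfigError(f"read_length exceeds insert size of {clone.clone_id}")
        row, col = grid.cell_of(i)
        n_reads = int(round(cfg.coverage * len(clone.seq) / cfg.read_length))
        starts = rng.integers(0, len(clone.seq) - cfg.read_length + 1, size=n_reads)
        to_row = rng.random(n_reads) < 0.5
        flip = rng.random(n_reads) < 0.5
        for j in range(n_reads):
            read_id = f"r{counter:07d}"
            counter += 1
            s = int(starts[j])
            seq = clone.seq[s: s + cfg.read_length].upper()
            if flip[j]:
                seq = _rc(seq)
            pool = pools[row] if to_row[j] else pools[grid.n_rows + col]
            pool.reads.append((read_id, seq))
            truth[read_id] = clone.clone_id
    return pools, truth


# ---------------------------------------------------------------------------
# probe tables


@dataclass
class ProbeTruth:
    single_copy_probes: list[str]
    multi_copy_probes: dict[str, int]
    expected_clones: list[str]
    pair_by_clone: dict[str, tuple[str, str]]


def simulate_probe_table(
    template: SeqRecordSet,
    clones: list[BacClone],
    n_probes: int,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ProbeHitTable, ProbeTruth]:
    """Overgo-style probe table with planted selectable structure.

    For every clone two single-copy probes are planted within 50 kb on the
    template, hybridizing to the clone plus a homolog-count background in
    the selectable 4-20 band.  Distractors include multi-copy probes,
    short-identity probes, out-of-band probes, and distant probe pairs.
    """
    import pandas as pd

    rng = rng or np.random.default_rng(cfg.seed + 3)
    chrom_lengths = {r.id: len(r.seq) for r in template}
    template_rows = []
    poly_rows = []
    truth = ProbeTruth([], {}, [], {})
    needed = 2 * len(clones) + 4
    if n_probes < needed:
        raise ConfigError(f"n_probes must be at least {needed}")
    pid = 0

    def next_pid() -> str:
        nonlocal pid
        pid += 1
        return f"probe{pid:04d}"

    for clone in clones:
        ct = clone.truth
        span = ct.t_end - ct.t_start
        gap_lo = max(2_000, min(20_000, span // 3))
        gap_hi = max(gap_lo + 1, min(45_000, span - 2_000))
        gap = int(rng.integers(gap_lo, gap_hi))
        pos_a = ct.t_start + int(rng.integers(500, span - gap - 500))
        pos_b = pos_a + gap
        pa, pb = next_pid(), next_pid()
        for p, pos in ((pa, pos_a), (pb, pos_b)):
            template_rows.append(
                {"probe_id": p, "chrom": ct.chrom, "position": pos,
                 "identical_length": int(rng.integers(36, 41))}
            )
            poly_rows.append({"probe_id": p, "clone_id": clone.clone_id})
            n_bg = int(rng.integers(10, 13)) - 1  # homolog count incl. this clone
            for b in range(n_bg):
                poly_rows.append({"probe_id": p, "clone_id": f"lib{pid:04d}_{b:02d}"})
            truth.single_copy_probes.append(p)
        truth.expected_clones.append(clone.clone_id)
        truth.pair_by_clone[clone.clone_id] = (pa, pb)

    chroms = list(chrom_lengths)
    while pid < n_probes:
        kind = int(rng.integers(0, 4))
        p = next_pid()
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, chrom_lengths[chrom]))
        if kind == 0:  # multi-copy on the template: fails single-copy filter
            n_hits = int(rng.integers(2, 6))
            for _ in range(n_hits):
                template_rows.append(
                    {"probe_id": p, "chrom": chrom,
                     "position": int(rng.integers(0, chrom_lengths[chrom])),
                     "identical_length": int(rng.integers(36, 41))}
                )
            truth.multi_copy_probes[p] = n_hits
            for b in range(int(rng.integers(8, 20))):
                poly_rows.append({"probe_id": p, "clone_id": f"lib{pid:04d}_{b:02d}"})
        elif kind == 1:  # identical length below threshold
            template_rows.append(
                {"probe_id": p, "chrom": chrom, "position": pos,
                 "identical_length": int(rng.integers(25, 35))}
            )
            for b in range(int(rng.integers(4, 12))):
                poly_rows.append({"probe_id": p, "clone_id": f"lib{pid:04d}_{b:02d}"})
        elif kind == 2:  # single-copy but hybridization count out of band
            template_rows.append(
                {"probe_id": p, "chrom": chrom, "position": pos,
                 "identical_length": int(rng.integers(36, 41))}
            )
            n_hits = 2 if rng.random() < 0.5 else int(rng.integers(21, 30))
            for b in range(n_hits):
                poly_rows.append({"probe_id": p, "clone_id": f"lib{pid:04d}_{b:02d}"})
            truth.single_copy_probes.append(p)
        else:  # single-copy, in band, but no close partner probe
            template_rows.append(
                {"probe_id": p, "chrom": chrom, "position": pos,
                 "identical_length": int(rng.integers(36, 41))}
            )
            for b in range(int(rng.integers(4, 12))):
                poly_rows.append({"probe_id": p, "clone_id": f"lib{pid:04d}_{b:02d}"})
            truth.single_copy_probes.append(p)
    table = ProbeHitTable(
        template_hits=pd.DataFrame(template_rows),
        polyploid_counts=pd.DataFrame(poly_rows),
    )
    return table, truth


# ---------------------------------------------------------------------------
# assembly-stage helpers


def fragment_clone(
    clone: BacClone,
    n_pieces: int,
    rng: np.random.Generator,
    revcomp_fraction: float = 0.1,
    at_gene_boundaries: bool = True,
):
    """Cut a clone into shuffled, partly reverse-complemented contigs.

    Emulates a fragmented shotgun assembly.  With ``at_gene_boundaries``
    cut points fall between annotated gene locations so every piece keeps
    at least one gene anchor (requires n_pieces <= gene count).  Returns a
    ContigSet plus the truth list of (contig_id, clone_start, clone_end,
    orientation).
    """
    from .template_scaffolding import ContigSet

    L = len(clone.seq)
    if at_gene_boundaries:
        spans = sorted(clone.truth.gene_locations.values())
        if n_pieces > len(spans):
            raise ConfigError("more pieces than gene anchors")
        mids = [
            (spans[i][1] + spans[i + 1][0]) // 2 for i in range(len(spans) - 1)
        ]
        cuts = sorted(rng.choice(len(mids), size=n_pieces - 1, replace=False))
        bounds = [0] + [mids[c] for c in cuts] + [L]
    else:
        cuts = sorted(rng.choice(L - 2, size=n_pieces - 1, replace=False) + 1)
        bounds = [0] + [int(c) for c in cuts] + [L]
    pieces = []
    for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
        seq = clone.seq[a:b]
        orient = "-" if rng.random() < revcomp_fraction else "+"
        if orient == "-":
            seq = _rc(seq.upper())
        pieces.append((f"{clone.clone_id}_ctg{i:02d}", seq, a, b, orient))
    order = rng.permutation(len(pieces))
    shuffled = [pieces[i] for i in order]
    contigs = SeqRecordSet([SeqRecord(id=p[0], seq=p[1]) for p in shuffled])
    truth = [(p[0], p[2], p[3], p[4]) for p in shuffled]
    return ContigSet(clone.clone_id, contigs), truth


def soft_mask_template(
    template: SeqRecordSet, truth: TemplateTruth
) -> SeqRecordSet:
    """Lower-case the truth repeat intervals (mask before anchoring)."""
    masked = []
    for rec in template:
        arr = np.frombuffer(rec.seq.encode(), dtype=np.uint8).copy()
        for r in truth.repeats:
            if r.chrom == rec.id:
                seg = arr[r.start: r.end]
                up = (seg >= 65) & (seg <= 90)
                seg[up] += 32
        masked.append(SeqRecord(id=rec.id, seq=arr.tobytes().decode(), description=rec.description))
    return SeqRecordSet(masked)


# ---------------------------------------------------------------------------
# ortholog pair generator (for divergence-recovery experiments)


def simulate_ortholog_pairs(
    n_pairs: int,
    target_ks: float,
    seed: int,
    n_codons: int = 100,
    omega: float = 0.3,
) -> list[tuple[str, str]]:
    """CDS pairs evolved to a known synonymous divergence.

    The substitution rate is calibrated on an independent calibration draw;
    the returned pairs are then generated with a fresh stream, so measured
    median Ks is an honest recovery of the target, not a replay of the
    calibration.
    """
    rng = np.random.default_rng(seed)
    non_stop = [c for c in _ALL_CODONS if c not in STOP_CODONS]

    def random_cds(r, length=n_codons):
        idx = r.integers(0, len(non_stop), size=length - 2)
        return "ATG" + "".join(non_stop[i] for i in idx) + "TAA"

    # calibration uses its own, larger and longer draw so the transferred
    # rate is low-noise and independent of the returned pairs
    calib_rng = np.random.default_rng(seed + 7)
    calib_cds = [random_cds(calib_rng, 200) for _ in range(120)]
    p = calibrate_substitution_rate(calib_cds, target_ks, omega, seed + 13, tol=0.001)
    pairs = []
    for _ in range(n_pairs):
        cds = random_cds(rng)
        pairs.append((cds, _mutate_cds(cds, p, omega, rng)))
    return pairs
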