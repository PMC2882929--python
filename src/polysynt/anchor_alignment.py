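"""Seed-and-extend local alignment of query contigs against a template genome.

Anchors are high-scoring local alignments used downstream for contig
ordering, rearrangement classification and ortholog detection.  Exact
``seed_k``-mer matches on both strands are clustered by diagonal; each
cluster window is then aligned with a full affine-gap Smith-Waterman
(Biopython's PairwiseAligner), so a reported hit's raw score is exactly the
optimal local-alignment score of its reported interval pair.  Raw scores are
converted to bits with the Karlin-Altschul form

    bit = (lambda * raw - ln K) / ln 2

and hits at or below ``min_bit`` (default 200, the collinearity filter
threshold) are discarded.  Soft-masked (lower-case) template or query bases
are excluded from seeding but participate in extension.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log

import numpy as np
from Bio.Align import PairwiseAligner

from .io_formats import SeqRecordSet

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AlignParams:
    seed_k: int = 13
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5  # charged once per gap, on top of gap_extend per base
    gap_extend: int = -2
    x_drop: int = 100  # window margin around a seed cluster, bp
    split_gap: int = 100  # alignments are split at internal gaps above this
    lam: float = 1.28
    K: float = 0.46
    min_bit: float = 200.0
    block_size: int = 2000  # max query span aligned in one window
    diag_band: int = 100  # seeds within this diagonal spread share a cluster
    cluster_gap: int = 2000  # max template gap between seeds of a cluster
    run_gap: int = 400  # seed runs split at larger q/t gaps (own windows)
    max_seed_occ: int = 40  # k-mers more frequent than this are not seeded

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.min_bit < 0:
            raise ValueError("min_bit must be >= 0")


@dataclass(frozen=True)
class AnchorHit:
    """A local alignment between query and template (0-based half-open)."""

    query_id: str
    q_start: int
    q_end: int
    template_chrom: str
    t_start: int
    t_end: int
    strand: str  # '+': query forward matches template; '-': query revcomp does
    raw_score: float
    bit_score: float
    identity: float

    def q_span(self) -> int:
        return self.q_end - self.q_start

    def t_span(self) -> int:
        return self.t_end - self.t_start


def bit_score(raw: float, params: AlignParams) -> float:
    return (params.lam * raw - log(params.K)) / log(2.0)


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i  # lowercase (masked) stays 255: excluded from seeding


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (positions, codes) of all k-mers made only of unmasked ACGT."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    valid = enc != 255
    ok = np.ones(n, dtype=bool)
    bad = ~valid
    if bad.any():
        # a window is valid iff it contains no invalid base
        cs = np.concatenate([[0], np.cumsum(bad)])
        ok = (cs[k:] - cs[:-k]) == 0
    codes = np.zeros(n, dtype=np.int64)
    e = np.where(valid, enc, 0).astype(np.int64)
    for j in range(k):
        codes = (codes << 2) | e[j: j + n]
    pos = np.nonzero(ok)[0]
    return pos, codes[ok]


class _TemplateIndex:
    def __init__(self, seqs: SeqRecordSet, k: int, max_occ: int):
        self.k = k
        self.entries = []  # (chrom, sorted codes, positions ordered by code)
        for rec in seqs:
            pos, codes = _kmer_codes(_encode(rec.seq), k)
            order = np.argsort(codes, kind="stable")
            self.entries.append((rec.id, codes[order], pos[order]))
        self.max_occ = max_occ

    def matches(self, qpos: np.ndarray, qcodes: np.ndarray):
        """Yield (chrom, query_positions, template_positions) seed matches."""
        for chrom, codes, pos in self.entries:
            lo = np.searchsorted(codes, qcodes, side="left")
            hi = np.searchsorted(codes, qcodes, side="right")
            occ = hi - lo
            keep = (occ > 0) & (occ <= self.max_occ)
            if not keep.any():
                continue
            reps = occ[keep]
            q_rep = np.repeat(qpos[keep], reps)
            starts = lo[keep]
            t_idx = np.concatenate(
                [np.arange(s, s + r) for s, r in zip(starts, reps)]
            )
            yield chrom, q_rep, pos[t_idx]


def _cluster_seeds(qpos: np.ndarray, tpos: np.ndarray, params: AlignParams):
    """Group seed matches into diagonal-banded, template-contiguous clusters."""
    diag = tpos - qpos
    order = np.lexsort((tpos, diag))
    qpos, tpos, diag = qpos[order], tpos[order], diag[order]
    bands = []
    start = 0
    for i in range(1, len(diag) + 1):
        if i == len(diag) or diag[i] - diag[i - 1] > params.diag_band:
            bands.append((qpos[start:i], tpos[start:i]))
            start = i
    clusters = []
    for q, t in bands:
        t_order = np.argsort(t, kind="stable")
        q, t = q[t_order], t[t_order]
        s = 0
        for i in range(1, len(t) + 1):
            # split into runs so every locally alignable stretch gets its own
            # window (a window reports only its best local alignment)
            if (
                i == len(t)
                or t[i] - t[i - 1] > params.run_gap
                or abs(int(q[i]) - int(q[i - 1])) > params.run_gap
            ):
                clusters.append((np.sort(q[s:i]), t[s:i]))
                s = i
    return clusters


def _local_aligner(params: AlignParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def _window_blocks(q: np.ndarray, t: np.ndarray, k: int, params: AlignParams):
    """Split a cluster into butt-joined windows of at most block_size query bp.

    Interior junctions sit at the midpoint between the flanking seeds of
    adjacent blocks so windows tile the cluster without overlap; the outer
    ends get the x_drop margin in the caller.
    """
    spans = []
    start = 0
    for i in range(1, len(q) + 1):
        if (
            i == len(q)
            or q[i] + k - q[start] > params.block_size
            or t[i] + k - t[start] > 2 * params.block_size
        ):
            spans.append((q[start], q[i - 1] + k, t[start], t[i - 1] + k))
            start = i
    blocks = []
    for bi, (q_lo, q_hi, t_lo, t_hi) in enumerate(spans):
        if bi > 0:
            q_lo = (spans[bi - 1][1] + q_lo) // 2
            t_lo = (spans[bi - 1][3] + t_lo) // 2
        if bi < len(spans) - 1:
            q_hi = (q_hi + spans[bi + 1][0]) // 2
            t_hi = (t_hi + spans[bi + 1][2]) // 2
        blocks.append((q_lo, q_hi, t_lo, t_hi, bi == 0, bi == len(spans) - 1))
    return blocks


def _align_window(
    aligner: PairwiseAligner,
    params: AlignParams,
    qseq: str,
    tseq: str,
    q_lo: int,
    q_hi: int,
    t_lo: int,
    t_hi: int,
) -> list[tuple[float, int, int, int, int, float]]:
    """Best local alignment of the window, split at internal gaps larger
    than split_gap so each returned part is contiguously aligned territory."""
    sub_q = qseq[q_lo:q_hi].upper()
    sub_t = tseq[t_lo:t_hi].upper()
    if not sub_q or not sub_t:
        return []
    alns = aligner.align(sub_q, sub_t)
    if alns.score <= 0:
        return []
    aln = alns[0]
    coord = aln.coordinates
    parts: list[tuple[float, int, int, int, int, float]] = []
    score = 0.0
    matches = cols = 0
    qs = ts = qe = te = None
    gap_first = params.gap_open + params.gap_extend

    def _close():
        nonlocal score, matches, cols, qs, ts, qe, te
        if qs is not None and score > 0 and cols > 0:
            parts.append(
                (score, q_lo + qs, q_lo + qe, t_lo + ts, t_lo + te, matches / cols)
            )
        score, matches, cols, qs, ts, qe, te = 0.0, 0, 0, None, None, None, None

    pending_gap_cost = 0.0
    pending_gap_cols = 0
    for kk in range(coord.shape[1] - 1):
        a0, a1 = int(coord[0, kk]), int(coord[0, kk + 1])
        b0, b1 = int(coord[1, kk]), int(coord[1, kk + 1])
        if a1 > a0 and b1 > b0:  # aligned block
            if qs is None:
                qs, ts = a0, b0
            score += pending_gap_cost
            cols += pending_gap_cols
            pending_gap_cost, pending_gap_cols = 0.0, 0
            sa, sb = sub_q[a0:a1], sub_t[b0:b1]
            m = sum(x == y for x, y in zip(sa, sb))
            matches += m
            cols += a1 - a0
            score += m * params.match + (a1 - a0 - m) * params.mismatch
            qe, te = a1, b1
        else:  # gap block
            glen = max(a1 - a0, b1 - b0)
            if glen > params.split_gap or qs is None:
                _close()
                pending_gap_cost, pending_gap_cols = 0.0, 0
            else:
                pending_gap_cost += gap_first + (glen - 1) * params.gap_extend
                pending_gap_cols += glen
    _close()
    return parts


def seed_extend_align(
    query: SeqRecordSet, template: SeqRecordSet, params: AlignParams | None = None
) -> list[AnchorHit]:
    """Align every query record against the template; return filtered hits.

    Output order is deterministic: template chromosome, template start,
    query start.
    """
    params = params or AlignParams()
    k = params.seed_k
    index = _TemplateIndex(template, k, params.max_seed_occ)
    aligner = _local_aligner(params)
    tseqs = {rec.id: rec.seq for rec in template}
    hits: list[AnchorHit] = []
    for rec in query:
        if len(rec.seq) < k:
            warnings.warn(f"query {rec.id} shorter than seed_k; skipped")
            continue
        for strand in "+-":
            qseq = rec.seq if strand == "+" else revcomp(rec.seq)
            qpos, qcodes = _kmer_codes(_encode(qseq), k)
            if len(qpos) == 0:
                continue
            for chrom, q_m, t_m in index.matches(qpos, qcodes):
                for q, t in _cluster_seeds(q_m, t_m, params):
                    for q_lo, q_hi, t_lo, t_hi, first, last in _window_blocks(
                        q, t, k, params
                    ):
                        m = params.x_drop
                        parts = _align_window(
                            aligner,
                            params,
                            qseq,
                            tseqs[chrom],
                            max(0, q_lo - m) if first else q_lo,
                            min(len(qseq), q_hi + m) if last else q_hi,
                            max(0, t_lo - m) if first else t_lo,
                            min(len(tseqs[chrom]), t_hi + m) if last else t_hi,
                        )
                        for raw, qs, qe, ts, te, ident in parts:
                            bits = bit_score(raw, params)
                            if strand == "-":
                                qs, qe = len(qseq) - qe, len(qseq) - qs
                            hits.append(
                                AnchorHit(
                                    query_id=rec.id,
                                    q_start=qs,
                                    q_end=qe,
                                    template_chrom=chrom,
                                    t_start=ts,
                                    t_end=te,
                                    strand=strand,
                                    raw_score=raw,
                                    bit_score=bits,
                                    identity=ident,
                                )
                            )
    hits = _merge_abutting(hits, params)
    hits = [h for h in hits if h.bit_score > params.min_bit]
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (h.template_chrom, h.t_start, h.q_start, h.strand))
    return hits


def _merge_abutting(hits: list[AnchorHit], params: AlignParams) -> list[AnchorHit]:
    """Fuse window hits that butt-join exactly on both axes (same diagonal run).

    For a gap-free junction the scores are additive, so the fused raw score
    is still the score of a single local alignment of the fused intervals.
    """
    out: list[AnchorHit] = []
    open_ends: dict[tuple, int] = {}  # (key, t_end, q_boundary) -> index in out

    def _key(h: AnchorHit) -> tuple:
        return (h.query_id, h.template_chrom, h.strand)

    for h in sorted(hits, key=lambda h: (h.template_chrom, h.t_start, h.q_start)):
        q_in = h.q_start if h.strand == "+" else h.q_end
        probe = (_key(h), int(h.t_start), int(q_in))
        if probe in open_ends:
            i = open_ends.pop(probe)
            g = out[i]
            w_g, w_h = g.t_span(), h.t_span()
            raw = g.raw_score + h.raw_score
            merged = AnchorHit(
                query_id=g.query_id,
                q_start=min(g.q_start, h.q_start),
                q_end=max(g.q_end, h.q_end),
                template_chrom=g.template_chrom,
                t_start=g.t_start,
                t_end=h.t_end,
                strand=g.strand,
                raw_score=raw,
                bit_score=bit_score(raw, params),
                identity=(g.identity * w_g + h.identity * w_h) / (w_g + w_h),
            )
            out[i] = merged
            q_out = merged.q_end if merged.strand == "+" else merged.q_start
            open_ends[(_key(merged), int(merged.t_end), int(q_out))] = i
        else:
            out.append(h)
            q_out = h.q_end if h.strand == "+" else h.q_start
            open_ends[(_key(h), int(h.t_end), int(q_out))] = len(out) - 1
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _dedupe_hits(hits: list[AnchorHit]) -> list[AnchorHit]:
    """Drop hits mostly contained (>=90% both axes) in a higher-scoring hit."""
    kept: list[AnchorHit] = []
    for h in sorted(hits, key=lambda h: -h.raw_score):
        redundant = False
        for g in kept:
            if g.query_id != h.query_id or g.template_chrom != h.template_chrom:
                continue
            if g.strand != h.strand:
                continue
            qo = _overlap(g.q_start, g.q_end, h.q_start, h.q_end)
            to = _overlap(g.t_start, g.t_end, h.t_start, h.t_end)
            if qo >= 0.9 * h.q_span() and to >= 0.9 * h.t_span():
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


# ---------------------------------------------------------------------------
# collinear chaining


@dataclass
class ChainResult:
    chain: list[AnchorHit] = field(default_factory=list)
    off_chain: list[AnchorHit] = field(default_factory=list)

    @property
    def weight(self) -> float:
        return sum(h.bit_score for h in self.chain)

    @property
    def chrom(self) -> str | None:
        return self.chain[0].template_chrom if self.chain else None

    @property
    def strand(self) -> str | None:
        return self.chain[0].strand if self.chain else None


def _chain_group(hits: list[AnchorHit], max_gap: int) -> tuple[float, list[AnchorHit]]:
    """Maximum bit-weight collinear chain within one (chrom, strand) group."""
    strand = hits[0].strand
    # On '-' hits the query axis runs backwards along the template; reflect it
    # so collinearity is monotone increase on both axes for either strand.
    def qkey(h: AnchorHit) -> tuple[int, int]:
        if strand == "+":
            return h.q_start, h.q_end
        return -h.q_end, -h.q_start

    hits = sorted(hits, key=lambda h: (h.t_start, qkey(h)[0]))
    n = len(hits)
    best = [h.bit_score for h in hits]
    prev = [-1] * n
    slack = 50  # tolerated bp of overlap between adjacent chained anchors
    for i in range(n):
        qi0, _ = qkey(hits[i])
        for j in range(i):
            qj0, qj1 = qkey(hits[j])
            if hits[j].t_end > hits[i].t_start + slack:
                continue
            if qj1 > qi0 + slack:
                continue
            if hits[i].t_start - hits[j].t_end > max_gap:
                continue
            if qi0 - qj1 > max_gap:
                continue
            cand = best[j] + hits[i].bit_score
            if cand > best[i] + 1e-9:
                best[i] = cand
                prev[i] = j
    end = max(range(n), key=lambda i: (best[i], -hits[i].t_start))
    chain = []
    i = end
    while i != -1:
        chain.append(hits[i])
        i = prev[i]
    chain.reverse()
    return best[end], chain


def chain_anchors(hits: list[AnchorHit], max_gap: int = 20000) -> ChainResult:
    """Best collinear chain over all (template_chrom, strand) groups.

    Hits must come from a single query.  Ties between equally weighted
    chains break toward the leftmost template coordinate.
    """
    if not hits:
        return ChainResult()
    groups: dict[tuple[str, str], list[AnchorHit]] = {}
    for h in hits:
        groups.setdefault((h.template_chrom, h.strand), []).append(h)
    best_weight = -1.0
    best_chain: list[AnchorHit] = []
    for key in sorted(groups):
        w, chain = _chain_group(groups[key], max_gap)
        if w > best_weight + 1e-9 or (
            abs(w - best_weight) <= 1e-9
            and chain
            and best_chain
            and chain[0].t_start < best_chain[0].t_start
        ):
            best_weight, best_chain = w, chain
    in_chain = set(id(h) for h in best_chain)
    off = [h for h in hits if id(h) not in in_chain]
    return ChainResult(chain=best_chain, off_chain=off)
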