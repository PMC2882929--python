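"""Classification of small-scale rearrangements against the collinear frame.

For one clone, the maximum-weight collinear chain of anchor hits defines
the syntenic frame.  Hits that pass the bit-score filter but fall off the
chain are evidence of structural change and are classified as:

* ``duplication_query``     extra query copy of a template locus (two query
                            intervals chain to one template interval),
* ``duplication_template``  extra template copy for one query interval,
* ``inversion``             opposite strand, template position inside the
                            frame's span,
* ``translocation``         same strand, template position outside the
                            frame or violating collinear order,
* ``inverted_translocation`` opposite strand and out-of-place.

Orientation polarity is reported relative to the template; without an
outgroup the genome of origin of an inversion cannot be inferred, which is
surfaced as a report caveat rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .anchor_alignment import AnchorHit, chain_anchors
from .io_formats import FeatureTable

EVENT_CLASSES = (
    "translocation",
    "inverted_translocation",
    "inversion",
    "duplication_query",
    "duplication_template",
)


@dataclass(frozen=True)
class RearrangementParams:
    min_bit: float = 200.0
    max_collinear_gap: int = 20_000
    reciprocal_overlap: float = 0.5  # duplication-copy interval agreement
    merge_gap: int = 150  # off-chain blocks closer than this fuse into one event


@dataclass(frozen=True)
class RearrangementEvent:
    event_class: str
    query_id: str
    q_start: int
    q_end: int
    template_chrom: str
    t_start: int
    t_end: int
    length: int  # aligned bp of the block (duplications: bp of the extra copy)
    bit_score: float


def _r_overlap(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = max(0, min(a1, b1) - max(a0, b0))
    if inter == 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _covered_fraction(lo: int, hi: int, intervals: list[tuple[int, int]]) -> float:
    """Fraction of [lo, hi) covered by the union of intervals."""
    if hi <= lo:
        return 0.0
    covered = 0
    pos = lo
    for s, e in sorted(intervals):
        s, e = max(s, pos), min(e, hi)
        if e > s:
            covered += e - s
            pos = e
    return covered / (hi - lo)


def _merge_blocks(off: list[AnchorHit], merge_gap: int) -> list[list[AnchorHit]]:
    """Fuse off-chain hits that continue each other into one event block."""
    blocks: list[list[AnchorHit]] = []
    for h in sorted(off, key=lambda h: (h.template_chrom, h.strand, h.t_start, h.q_start)):
        merged = False
        for blk in blocks:
            g = blk[-1]
            if (
                g.template_chrom == h.template_chrom
                and g.strand == h.strand
                and 0 <= h.t_start - g.t_end <= merge_gap
            ):
                q_gap = (
                    h.q_start - g.q_end if h.strand == "+" else g.q_start - h.q_end
                )
                if 0 <= q_gap <= merge_gap:
                    blk.append(h)
                    merged = True
                    break
        if not merged:
            blocks.append([h])
    return blocks


def classify_rearrangements(
    hits: list[AnchorHit], params: RearrangementParams | None = None
) -> list[RearrangementEvent]:
    """Classify off-chain structure of one clone's hits into event classes."""
    params = params or RearrangementParams()
    hits = [h for h in hits if h.bit_score > params.min_bit]
    if not hits:
        return []
    frame = chain_anchors(hits, params.max_collinear_gap)
    if not frame.chain:
        return []
    chain = frame.chain
    f_chrom, f_strand = frame.chrom, frame.strand
    f_t_lo = min(h.t_start for h in chain)
    f_t_hi = max(h.t_end for h in chain)
    query_id = chain[0].query_id
    events: list[RearrangementEvent] = []
    for blk in _merge_blocks(frame.off_chain, params.merge_gap):
        q0 = min(h.q_start for h in blk)
        q1 = max(h.q_end for h in blk)
        t0 = min(h.t_start for h in blk)
        t1 = max(h.t_end for h in blk)
        strand = blk[0].strand
        chrom = blk[0].template_chrom
        bits = sum(h.bit_score for h in blk)
        aligned_q = sum(h.q_span() for h in blk)
        aligned_t = sum(h.t_span() for h in blk)
        on_frame_chrom = chrom == f_chrom
        # duplications: the block re-covers chain territory on one axis only
        chain_t = [(c.t_start, c.t_end) for c in chain]
        chain_q = [(c.q_start, c.q_end) for c in chain]
        cov_t = _covered_fraction(t0, t1, chain_t) if on_frame_chrom else 0.0
        cov_q = _covered_fraction(q0, q1, chain_q)
        margin = params.merge_gap * 10
        inside_frame = (
            on_frame_chrom and t0 >= f_t_lo - margin and t1 <= f_t_hi + margin
        )
        thr = params.reciprocal_overlap
        if cov_t >= thr and cov_q < thr / 2:
            cls, length = "duplication_query", aligned_q
        elif cov_q >= thr and cov_t < thr / 2:
            cls, length = "duplication_template", aligned_t
        elif strand != f_strand and inside_frame:
            cls, length = "inversion", aligned_q
        elif strand != f_strand:
            cls, length = "inverted_translocation", aligned_q
        else:
            cls, length = "translocation", aligned_q
        events.append(
            RearrangementEvent(
                event_class=cls,
                query_id=query_id,
                q_start=q0,
                q_end=q1,
                template_chrom=chrom,
                t_start=t0,
                t_end=t1,
                length=length,
                bit_score=bits,
            )
        )
    events.sort(key=lambda e: (e.query_id, e.q_start, e.t_start))
    return events


@dataclass
class RearrangementSummary:
    table: pd.DataFrame  # per-class rows plus a Total row

    @property
    def total_events(self) -> int:
        return int(self.table.loc[self.table["event_class"] == "Total", "n_events"].iloc[0])


def summarize_events(events: list[RearrangementEvent]) -> RearrangementSummary:
    """Per-class totals with integer-rounded mean lengths and a grand total."""
    rows = []
    for cls in EVENT_CLASSES:
        cls_events = [e for e in events if e.event_class == cls]
        total = sum(e.length for e in cls_events)
        n = len(cls_events)
        rows.append(
            {
                "event_class": cls,
                "total_bp": total,
                "n_events": n,
                "mean_bp": round(total / n) if n else 0,
            }
        )
    g_total = sum(r["total_bp"] for r in rows)
    g_n = sum(r["n_events"] for r in rows)
    rows.append(
        {
            "event_class": "Total",
            "total_bp": g_total,
            "n_events": g_n,
            "mean_bp": round(g_total / g_n) if g_n else 0,
        }
    )
    return RearrangementSummary(pd.DataFrame(rows))


def detect_tandem_duplications(
    genes_query: FeatureTable,
    genes_template: FeatureTable,
    orthologs: list[tuple[str, str]],
    max_tandem_gap: int = 20_000,
) -> pd.DataFrame:
    """Unequal tandem copy counts between the two genomes.

    ``orthologs`` is a many-to-many list of (query gene id, template gene
    id) pairs; connected components define gene families.  A family is
    reported when its copy counts differ between genomes and the multi-copy
    side forms a tandem array (same sequence and strand, adjacent copies at
    most ``max_tandem_gap`` apart).
    """
    q_feats = {f.attr.get("ID", ""): f for f in genes_query}
    t_feats = {f.attr.get("ID", ""): f for f in genes_template}
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for qg, tg in orthologs:
        union(("q", qg), ("t", tg))
    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in parent:
        components.setdefault(find(node), []).append(node)

    def is_tandem(feats):
        if len(feats) <= 1:
            return True
        feats = sorted(feats, key=lambda f: (f.seq_id, f.start))
        for a, b in zip(feats, feats[1:]):
            if a.seq_id != b.seq_id or a.strand != b.strand:
                return False
            if b.start - a.end > max_tandem_gap:
                return False
        return True

    rows = []
    for comp in components.values():
        q_ids = sorted(g for kind, g in comp if kind == "q" and g in q_feats)
        t_ids = sorted(g for kind, g in comp if kind == "t" and g in t_feats)
        if not q_ids or not t_ids or len(q_ids) == len(t_ids):
            continue
        if not is_tandem([q_feats[g] for g in q_ids]):
            continue
        if not is_tandem([t_feats[g] for g in t_ids]):
            continue
        rows.append(
            {
                "family": t_ids[0],
                "query_genes": ",".join(q_ids),
                "template_genes": ",".join(t_ids),
                "copies_query": len(q_ids),
                "copies_template": len(t_ids),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["family", "query_genes", "template_genes", "copies_query", "copies_template"],
    )
    return df.sort_values("family").reset_index(drop=True) if len(df) else df
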