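"""Template-guided ordering of assembly contigs and synteny summaries.

A related diploid genome serves as the ordering template: each contig's
anchor alignments are chained per (chromosome, strand) locus, the dominant
chain fixes the contig's position and orientation, ambiguously placed
contigs (competitive second locus) are left unordered, and inter-contig
gaps are estimated from the template projection, which the template's
gapless sequence makes possible.  Summary fractions follow the clone-table
arithmetic: ordered bp over insert bp, aligned (spanned) query bp over
insert bp, and relative template expansion over the aligned regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .anchor_alignment import AlignParams, AnchorHit, chain_anchors, seed_extend_align
from .io_formats import SeqRecordSet


@dataclass(frozen=True)
class ScaffoldParams:
    min_containment: float = 0.9  # identity-weighted coverage for dedup removal
    ambiguity_ratio: float = 2.0  # best/second-best locus bit-weight ratio
    max_chain_gap: int = 20_000  # bp tolerated between chained anchors
    closable_gap: int = 2_000  # gaps strictly below this are primer-closable
    align: AlignParams = field(default_factory=AlignParams)


@dataclass
class ContigSet:
    clone_id: str
    contigs: SeqRecordSet
    provenance: str = ""


@dataclass
class PlacedContig:
    contig_id: str
    orientation: str  # '+' or '-'
    template_chrom: str
    t_start: int  # projected template interval, 0-based half-open
    t_end: int
    aligned_query_bp: int
    chain_weight: float
    t_center: float = 0.0  # bit-weighted centre of the chain's anchors
    estimated_gap_after: int | None = None
    overlap_suspected: bool = False
    closable: bool = False


@dataclass
class ContigLayout:
    clone_id: str
    placed: list[PlacedContig] = field(default_factory=list)
    unplaced: list[tuple[str, str]] = field(default_factory=list)  # (contig_id, reason)
    spanned_query_bp: int = 0
    spanned_template_bp: int = 0
    ordered_bp: int = 0
    validated: bool = False

    def validate(self) -> "ContigLayout":
        prev_end = None
        for p in self.placed:
            if p.t_start >= p.t_end:
                raise ValueError(f"{p.contig_id}: empty projection")
            if prev_end is not None and p.t_start < prev_end:
                raise ValueError(f"{p.contig_id}: projections overlap after resolution")
            prev_end = p.t_end
        self.validated = True
        return self


def dedupe_contigs(
    contigs: ContigSet, min_containment: float = 0.9, align: AlignParams | None = None
) -> ContigSet:
    """Drop contigs contained in a longer kept contig (redundant assemblies).

    Containment is identity-weighted alignment coverage of the shorter
    contig by the longer one, computed with the in-package aligner applied
    contig-vs-contig.
    """
    align = align or AlignParams()
    seqs = contigs.contigs
    if len(seqs) <= 1:
        return ContigSet(contigs.clone_id, seqs, contigs.provenance)
    hits = seed_extend_align(seqs, seqs, align)
    by_pair: dict[tuple[str, str], list[AnchorHit]] = {}
    for h in hits:
        if h.query_id != h.template_chrom:
            by_pair.setdefault((h.query_id, h.template_chrom), []).append(h)
    lengths = {r.id: len(r.seq) for r in seqs}
    order = sorted(seqs.ids(), key=lambda i: (-lengths[i], i))
    kept: list[str] = []
    removed: set[str] = set()
    for cid in order:
        contained = False
        for other in kept:
            cover = 0.0
            covered_to = 0  # hits are t-sorted; approximate union by clipping
            for h in sorted(by_pair.get((cid, other), []), key=lambda h: h.q_start):
                lo = max(h.q_start, covered_to)
                if h.q_end > lo:
                    cover += (h.q_end - lo) * h.identity
                    covered_to = h.q_end
            if cover / lengths[cid] >= min_containment:
                contained = True
                break
        if contained:
            removed.add(cid)
        else:
            kept.append(cid)
    keep_records = [r for r in seqs if r.id not in removed]
    return ContigSet(contigs.clone_id, SeqRecordSet(keep_records), contigs.provenance)


def _loci_weights(hits: list[AnchorHit], max_gap: int):
    """Best chain per (chrom, strand) locus, heaviest first."""
    groups: dict[tuple[str, str], list[AnchorHit]] = {}
    for h in hits:
        groups.setdefault((h.template_chrom, h.strand), []).append(h)
    chains = []
    for key in sorted(groups):
        res = chain_anchors(groups[key], max_gap)
        if res.chain:
            chains.append(res)
        # a second locus on the same chromosome/strand also competes
        if res.off_chain:
            res2 = chain_anchors(res.off_chain, max_gap)
            if res2.chain:
                chains.append(res2)
    chains.sort(key=lambda c: -c.weight)
    return chains


def order_contigs(
    contigs: ContigSet, template: SeqRecordSet, params: ScaffoldParams | None = None
) -> ContigLayout:
    """Place, orient and sort contigs by their dominant template locus.

    Contigs with no anchors are unplaced(no_anchor); contigs whose best and
    second-best loci compete within the ambiguity ratio are
    unplaced(multi_locus); contigs disagreeing with the clone's dominant
    chromosome are unplaced(conflict).  Projections of placed contigs are
    made non-overlapping by trimming the lower-weight contig's projection.
    """
    params = params or ScaffoldParams()
    layout = ContigLayout(clone_id=contigs.clone_id)
    all_hits = seed_extend_align(contigs.contigs, template, params.align)
    hits_by_contig: dict[str, list[AnchorHit]] = {}
    for h in all_hits:
        hits_by_contig.setdefault(h.query_id, []).append(h)
    candidates: list[PlacedContig] = []
    for cid in contigs.contigs.ids():
        hits = hits_by_contig.get(cid, [])
        if not hits:
            layout.unplaced.append((cid, "no_anchor"))
            continue
        chains = _loci_weights(hits, params.max_chain_gap)
        best = chains[0]
        if len(chains) > 1 and chains[1].weight * params.ambiguity_ratio > best.weight:
            layout.unplaced.append((cid, "multi_locus"))
            continue
        t_start = min(h.t_start for h in best.chain)
        t_end = max(h.t_end for h in best.chain)
        center = sum(
            0.5 * (h.t_start + h.t_end) * h.bit_score for h in best.chain
        ) / best.weight
        candidates.append(
            PlacedContig(
                contig_id=cid,
                orientation=best.strand,
                template_chrom=best.chrom,
                t_start=t_start,
                t_end=t_end,
                aligned_query_bp=sum(h.q_span() for h in best.chain),
                chain_weight=best.weight,
                t_center=center,
            )
        )
    if not candidates:
        return layout.validate()
    # dominant chromosome by total anchored weight
    weight_by_chrom: dict[str, float] = {}
    for p in candidates:
        weight_by_chrom[p.template_chrom] = (
            weight_by_chrom.get(p.template_chrom, 0.0) + p.chain_weight
        )
    dominant = max(sorted(weight_by_chrom), key=lambda c: weight_by_chrom[c])
    placed = []
    for p in candidates:
        if p.template_chrom != dominant:
            layout.unplaced.append((p.contig_id, "conflict"))
        else:
            placed.append(p)
    # order by the bit-weighted centre of each chain: robust against a stray
    # duplicated-source anchor extending one projection edge
    placed.sort(key=lambda p: (p.t_center, p.t_start, p.contig_id))
    # resolve overlapping projections: trim the lower-weight projection
    for i in range(1, len(placed)):
        prev, cur = placed[i - 1], placed[i]
        if cur.t_start < prev.t_end:
            if cur.chain_weight >= prev.chain_weight:
                prev.t_end = max(prev.t_start + 1, cur.t_start)
            else:
                cur.t_start = min(cur.t_end - 1, prev.t_end)
    # final sweep: clamp any residual overlap (e.g. nested projections)
    cursor = None
    for p in placed:
        if cursor is not None and p.t_start < cursor:
            p.t_start = cursor
            if p.t_end <= p.t_start:
                p.t_end = p.t_start + 1
        cursor = p.t_end
    layout.placed = placed
    contig_lengths = {r.id: len(r.seq) for r in contigs.contigs}
    layout.ordered_bp = sum(contig_lengths[p.contig_id] for p in placed)
    layout.spanned_query_bp = sum(p.aligned_query_bp for p in placed)
    layout.spanned_template_bp = max(p.t_end for p in placed) - min(
        p.t_start for p in placed
    )
    return layout.validate()


def estimate_gaps(layout: ContigLayout, params: ScaffoldParams | None = None) -> ContigLayout:
    """Fill estimated inter-contig gaps from the template projection.

    The gap is the template distance between adjacent projected ends;
    negative estimates are flagged overlap_suspected, and gaps strictly
    below the closable threshold are flagged closable (primer-walkable).
    """
    params = params or ScaffoldParams()
    for i in range(len(layout.placed) - 1):
        cur, nxt = layout.placed[i], layout.placed[i + 1]
        gap = nxt.t_start - cur.t_end
        cur.estimated_gap_after = gap
        cur.overlap_suspected = gap < 0
        cur.closable = 0 <= gap < params.closable_gap
    if layout.placed:
        layout.placed[-1].estimated_gap_after = None
    return layout


@dataclass
class SyntenySummary:
    per_clone: pd.DataFrame
    insert_bp: int
    assembled_bp: int
    unambiguous_bp: int
    ordered_bp: int
    spanned_query_bp: int
    spanned_template_bp: int
    ordered_fraction: float
    aligned_fraction: float
    expansion_fraction: float

    def to_dataframe(self) -> pd.DataFrame:
        return self.per_clone


def summarize(
    layouts: list[ContigLayout],
    inserts_bp: dict[str, int],
    assembled_bp: dict[str, int] | None = None,
    unambiguous_bp: dict[str, int] | None = None,
    denominator: str = "insert",
) -> SyntenySummary:
    """Clone-table style totals and fractions.

    ordered_fraction = sum(ordered bp) / sum(insert bp)
    aligned_fraction = sum(spanned query bp) / sum(insert bp)
    expansion_fraction = (sum(spanned template) - sum(spanned query)) / sum(spanned query)

    ``denominator='unambiguous'`` switches the ordered/aligned denominators
    to the unambiguous-contig total instead of the insert estimate.
    """
    assembled_bp = assembled_bp or {}
    unambiguous_bp = unambiguous_bp or {}
    rows = []
    for lay in layouts:
        rows.append(
            {
                "clone_id": lay.clone_id,
                "insert_bp": inserts_bp.get(lay.clone_id, 0),
                "assembled_bp": assembled_bp.get(lay.clone_id, 0),
                "unambiguous_bp": unambiguous_bp.get(lay.clone_id, 0),
                "n_ordered_contigs": len(lay.placed),
                "n_unplaced_contigs": len(lay.unplaced),
                "ordered_bp": lay.ordered_bp,
                "spanned_query_bp": lay.spanned_query_bp,
                "spanned_template_bp": lay.spanned_template_bp,
            }
        )
    df = pd.DataFrame(rows)
    tot_insert = int(df["insert_bp"].sum())
    if tot_insert <= 0 and denominator == "insert":
        raise ValueError("zero total insert bp; fractions undefined")
    denom = (
        tot_insert if denominator == "insert" else int(df["unambiguous_bp"].sum())
    )
    if denom <= 0:
        raise ValueError("zero denominator; fractions undefined")
    tot_ordered = int(df["ordered_bp"].sum())
    tot_sq = int(df["spanned_query_bp"].sum())
    tot_st = int(df["spanned_template_bp"].sum())
    return SyntenySummary(
        per_clone=df,
        insert_bp=tot_insert,
        assembled_bp=int(df["assembled_bp"].sum()),
        unambiguous_bp=int(df["unambiguous_bp"].sum()),
        ordered_bp=tot_ordered,
        spanned_query_bp=tot_sq,
        spanned_template_bp=tot_st,
        ordered_fraction=tot_ordered / denom,
        aligned_fraction=tot_sq / denom,
        expansion_fraction=(tot_st - tot_sq) / tot_sq if tot_sq else float("nan"),
    )
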