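"""Codon-aware ortholog alignment, Nei-Gojobori (NG86) Ka/Ks, and clock dating.

The divergence time between two taxa is estimated as

    T = Ks_median / (2 * r)

with r the synonymous substitution rate per site per year (default 6.5e-9,
the commonly used grass-lineage rate), and Ks_median the median NG86
synonymous distance over a set of ortholog pairs.

NG86 here is the classic counting method: synonymous site fractions are the
per-position fractions of single-base changes that preserve the amino acid
(changes producing stop codons count as nonsynonymous, so S + N = 3 per
codon), multi-position codon differences are averaged over all substitution
orderings with pathways through stop codons excluded, and the Jukes-Cantor
correction d = -(3/4) ln(1 - (4/3) p) maps proportions to distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import log

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_STANDARD.stop_codons)


class SaturationError(ValueError):
    """Observed synonymous proportion >= 3/4; NG86 distance undefined."""


class AlignmentRejected(ValueError):
    """A pair failed the reliability screen (internal stop, short or weak alignment)."""


def translate(cds: str) -> str:
    return str(Seq(cds).translate(table=1))


def _aa(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _STANDARD.forward_table[codon]


@lru_cache(maxsize=1)
def _site_table() -> np.ndarray:
    """Per-codon synonymous site counts s(c); nonsynonymous is 3 - s(c)."""
    s = np.zeros(64)
    for i, codon in enumerate(CODONS):
        if codon in STOP_CODONS:
            s[i] = np.nan
            continue
        syn = 0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1:]
                if alt not in STOP_CODONS and _aa(alt) == _aa(codon):
                    syn += 1
        s[i] = syn / 3.0
    return s


@lru_cache(maxsize=1)
def _diff_tables() -> tuple[np.ndarray, np.ndarray]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts per codon pair.

    All orderings of the differing positions are enumerated; orderings that
    pass through a stop codon are excluded and the remainder reweighted.  In
    the rare case where every ordering is blocked the average over all
    orderings (ignoring the stop exclusion) is used.
    """
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i, c1 in enumerate(CODONS):
        if c1 in STOP_CODONS:
            sd[i, :] = nd[i, :] = np.nan
            continue
        for j, c2 in enumerate(CODONS):
            if c2 in STOP_CODONS:
                sd[i, j] = nd[i, j] = np.nan
                continue
            if i == j:
                continue
            sd[i, j], nd[i, j] = _pathway_average(c1, c2)
    return sd, nd


def _pathway_average(c1: str, c2: str) -> tuple[float, float]:
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    syn = nonsyn = 0.0
    for steps in usable:
        for a, b in steps:
            if a not in STOP_CODONS and b not in STOP_CODONS and _aa(a) == _aa(b):
                syn += 1
            else:
                nonsyn += 1
    n = len(usable)
    return syn / n, nonsyn / n


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class CodonAlignment:
    """Aligned codon columns for a pair of CDS; gap/ambiguous columns flagged."""

    codons_a: list[str]
    codons_b: list[str]
    counted: list[bool]  # False for columns with gaps or ambiguous bases
    protein_identity: float = 1.0
    aligned_residues: int = 0

    def counted_pairs(self) -> list[tuple[str, str]]:
        return [
            (a, b)
            for a, b, ok in zip(self.codons_a, self.codons_b, self.counted)
            if ok
        ]


def _protein_aligner(gap_open: float = -10.0, gap_extend: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _check_cds(cds: str, label: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise AlignmentRejected(f"{label}: CDS length {len(cds)} not divisible by 3")
    prot = translate(cds)
    if prot.endswith("*"):
        prot = prot[:-1]
        cds = cds[:-3]
    if "*" in prot:
        raise AlignmentRejected(f"{label}: internal stop codon")
    return cds


def align_codons(
    cds_a: str,
    cds_b: str,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
    min_aligned_residues: int = 50,
    min_identity: float = 0.5,
    check_reliability: bool = True,
) -> CodonAlignment:
    """Globally align the translations and back-map to a codon alignment.

    The protein alignment (Needleman-Wunsch, BLOSUM62, affine gaps) is
    expanded so each residue column becomes a codon triplet; protein gaps
    become codon gaps, preserving frame in both sequences.  Columns with a
    gap or an ambiguous base are flagged and excluded from NG86 counting.
    Unreliable pairs (short or weakly identical alignments) are rejected.
    """
    cds_a = _check_cds(cds_a, "cds_a")
    cds_b = _check_cds(cds_b, "cds_b")
    prot_a, prot_b = translate(cds_a), translate(cds_b)
    aln = _protein_aligner(gap_open, gap_extend).align(prot_a, prot_b)[0]
    coord = aln.coordinates
    codons_a: list[str] = []
    codons_b: list[str] = []
    matches = 0
    aligned = 0
    for k in range(coord.shape[1] - 1):
        a0, a1 = coord[0, k], coord[0, k + 1]
        b0, b1 = coord[1, k], coord[1, k + 1]
        if a1 > a0 and b1 > b0:  # aligned block
            for off in range(a1 - a0):
                ca = cds_a[3 * (a0 + off): 3 * (a0 + off) + 3]
                cb = cds_b[3 * (b0 + off): 3 * (b0 + off) + 3]
                codons_a.append(ca)
                codons_b.append(cb)
                aligned += 1
                if prot_a[a0 + off] == prot_b[b0 + off]:
                    matches += 1
        elif a1 > a0:  # gap in b
            for off in range(a1 - a0):
                codons_a.append(cds_a[3 * (a0 + off): 3 * (a0 + off) + 3])
                codons_b.append("---")
        else:  # gap in a
            for off in range(b1 - b0):
                codons_a.append("---")
                codons_b.append(cds_b[3 * (b0 + off): 3 * (b0 + off) + 3])
    identity = matches / aligned if aligned else 0.0
    if check_reliability and (aligned < min_aligned_residues or identity < min_identity):
        raise AlignmentRejected(
            f"unreliable alignment: {aligned} aligned residues, identity {identity:.2f}"
        )
    counted = [
        "-" not in ca and "-" not in cb
        and set(ca) <= set("ACGT") and set(cb) <= set("ACGT")
        for ca, cb in zip(codons_a, codons_b)
    ]
    return CodonAlignment(codons_a, codons_b, counted, identity, aligned)


# ---------------------------------------------------------------------------
# NG86


@dataclass(frozen=True)
class Ng86Result:
    Ks: float
    Ka: float
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; distance undefined")
    return -0.75 * log(1.0 - (4.0 / 3.0) * p) + 0.0  # normalize -0.0


def ng86(alignment: CodonAlignment) -> Ng86Result:
    """NG86 synonymous/nonsynonymous distances for a codon alignment."""
    pairs = alignment.counted_pairs()
    if not pairs:
        raise ValueError("no ungapped codon columns to count")
    sites = _site_table()
    sd_tab, nd_tab = _diff_tables()
    ia = np.array([CODON_INDEX[a] for a, _ in pairs])
    ib = np.array([CODON_INDEX[b] for _, b in pairs])
    S = float((sites[ia].sum() + sites[ib].sum()) / 2.0)
    N = 3.0 * len(pairs) - S
    Sd = float(sd_tab[ia, ib].sum())
    Nd = float(nd_tab[ia, ib].sum())
    if S <= 0:
        raise ValueError("zero synonymous sites; Ks undefined")
    pS, pN = Sd / S, Nd / N
    return Ng86Result(Ks=_jc(pS), Ka=_jc(pN), S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN)


def kaks_pair(cds_a: str, cds_b: str, **align_kwargs) -> Ng86Result:
    """Convenience: codon-align a CDS pair and run NG86."""
    return ng86(align_codons(cds_a, cds_b, **align_kwargs))


def kaks_table(pairs: list[tuple[str, str, str, str]], **align_kwargs) -> pd.DataFrame:
    """Per-pair NG86 table for (id_a, id_b, cds_a, cds_b) tuples.

    Rejected pairs appear with a ``rejected`` reason and NaN statistics,
    mirroring the practice of discarding unreliable alignments.
    """
    rows = []
    for id_a, id_b, cds_a, cds_b in pairs:
        row = {"gene_query": id_a, "gene_template": id_b, "rejected": ""}
        try:
            r = kaks_pair(cds_a, cds_b, **align_kwargs)
            row.update(
                Ks=r.Ks, Ka=r.Ka, S=r.S, N=r.N, Sd=r.Sd, Nd=r.Nd
            )
        except (AlignmentRejected, SaturationError, ValueError) as exc:
            row.update(Ks=np.nan, Ka=np.nan, S=np.nan, N=np.nan,
                       Sd=np.nan, Nd=np.nan, rejected=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# molecular clock


GRASS_SYNONYMOUS_RATE = 6.5e-9  # synonymous substitutions / site / year


@dataclass(frozen=True)
class DivergenceEstimate:
    n_pairs: int
    median_ks: float
    rate: float
    time_years: float
    time_mya: float


def lower_median(values: list[float]) -> float:
    """Median with the lower of the two central values for even counts."""
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def estimate_divergence(
    ks_values: list[float], rate: float = GRASS_SYNONYMOUS_RATE
) -> DivergenceEstimate:
    """Date a species split from ortholog Ks values: T = median(Ks) / (2 r)."""
    ks_values = [k for k in ks_values if k == k]  # drop NaN
    if not ks_values:
        raise ValueError("no Ks values to summarize")
    med = lower_median(ks_values)
    t_years = med / (2.0 * rate)
    return DivergenceEstimate(
        n_pairs=len(ks_values),
        median_ks=med,
        rate=rate,
        time_years=t_years,
        time_mya=round(t_years / 1e6, 1),
    )
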