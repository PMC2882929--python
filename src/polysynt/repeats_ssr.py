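"""Library-based repeat soft-masking and microsatellite (SSR) detection.

Repeat masking aligns a labelled library of consensus sequences against the
input with the in-package local aligner; bases claimed by a hit above
``min_bit_repeat`` are lower-cased and tallied per family, with overlapping
family claims resolved by bit score.  The family taxonomy is fixed so
summaries are comparable across runs; unknown library labels map to
``Unclassified``.  Tandem simple repeats and low-complexity windows
(Shannon entropy below a threshold) are tallied separately.

SSRs are perfect tandem repeats of a 1-6 bp primitive motif, reported as
maximal runs with canonicalized motifs and flanking sequence for primer
design.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from math import log2

import numpy as np
import pandas as pd

from .anchor_alignment import AlignParams, revcomp, seed_extend_align
from .io_formats import SeqRecord, SeqRecordSet

REPEAT_FAMILIES = (
    "SINE",
    "LINE/L1-CIN4",
    "LTR/Copia",
    "LTR/Gypsy-DIRS1",
    "DNA/hobo-Activator",
    "DNA/Tc1-Pogo",
    "DNA/En-Spm",
    "DNA/MuDR",
    "DNA/Tourist-Harbinger",
    "Unclassified",
)

DEFAULT_MIN_COPIES = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass
class RepeatLibrary:
    """Consensus sequences with family labels from the fixed taxonomy."""

    entries: list[tuple[str, str, str]] = field(default_factory=list)  # (name, family, consensus)

    def __post_init__(self) -> None:
        normalized = []
        for name, family, consensus in self.entries:
            if not consensus:
                raise ValueError(f"empty consensus for library entry {name!r}")
            if family not in REPEAT_FAMILIES:
                family = "Unclassified"
            normalized.append((name, family, consensus.upper()))
        self.entries = normalized

    def to_seqset(self) -> SeqRecordSet:
        return SeqRecordSet(
            [SeqRecord(id=name, seq=cons) for name, _fam, cons in self.entries]
        )

    def family_of(self, name: str) -> str:
        for n, fam, _ in self.entries:
            if n == name:
                return fam
        raise KeyError(name)


@dataclass
class RepeatSummary:
    family_bp: dict[str, int]
    simple_repeats_bp: int
    low_complexity_bp: int
    total_sequence_bp: int

    @property
    def masked_bp(self) -> int:
        return sum(self.family_bp.values()) + self.simple_repeats_bp + self.low_complexity_bp

    def fraction(self, bp: int) -> float:
        return bp / self.total_sequence_bp if self.total_sequence_bp else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "category": fam,
                "length_bp": self.family_bp.get(fam, 0),
                "pct_of_sequence": round(100 * self.fraction(self.family_bp.get(fam, 0)), 2),
            }
            for fam in REPEAT_FAMILIES
        ]
        rows.append(
            {
                "category": "Simple repeats",
                "length_bp": self.simple_repeats_bp,
                "pct_of_sequence": round(100 * self.fraction(self.simple_repeats_bp), 2),
            }
        )
        rows.append(
            {
                "category": "Low complexity",
                "length_bp": self.low_complexity_bp,
                "pct_of_sequence": round(100 * self.fraction(self.low_complexity_bp), 2),
            }
        )
        rows.append(
            {
                "category": "Total",
                "length_bp": self.masked_bp,
                "pct_of_sequence": round(100 * self.fraction(self.masked_bp), 2),
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RepeatMaskParams:
    min_bit_repeat: float = 50.0
    entropy_threshold: float = 1.5  # bits/base
    entropy_window: int = 64
    seed_k: int = 13


def mask_repeats(
    seqs: SeqRecordSet,
    library: RepeatLibrary,
    params: RepeatMaskParams | None = None,
    ssr_min_copies: dict[int, int] | None = None,
) -> tuple[SeqRecordSet, RepeatSummary]:
    """Soft-mask library repeats, simple repeats and low-complexity runs.

    Returns the masked sequence set and a per-family accounting of masked bp
    relative to the total input length.  Masking is idempotent: masked bases
    are excluded from seeding, so a second pass changes nothing.
    """
    params = params or RepeatMaskParams()
    total_bp = sum(len(r.seq) for r in seqs)
    claims: dict[str, np.ndarray] = {
        r.id: np.full(len(r.seq), -1, dtype=np.int32) for r in seqs
    }  # -1 free, >=0 family index, -2 simple, -3 low-complexity

    if library.entries:
        aln_params = AlignParams(min_bit=params.min_bit_repeat, seed_k=params.seed_k)
        hits = seed_extend_align(library.to_seqset(), seqs, aln_params)
        for h in sorted(hits, key=lambda h: (-h.bit_score, h.template_chrom, h.t_start)):
            fam_idx = REPEAT_FAMILIES.index(library.family_of(h.query_id))
            arr = claims[h.template_chrom]
            seg = arr[h.t_start: h.t_end]
            seg[seg == -1] = fam_idx
    # tandem simple repeats
    ssrs = detect_ssrs(seqs, min_copies=ssr_min_copies or DEFAULT_MIN_COPIES, flank_len=0)
    for locus in ssrs:
        arr = claims[locus.seq_id]
        seg = arr[locus.start: locus.end]
        seg[seg == -1] = -2
    # low-complexity windows
    for rec in seqs:
        arr = claims[rec.id]
        for lo, hi in low_complexity_windows(
            rec.seq, params.entropy_window, params.entropy_threshold
        ):
            seg = arr[lo:hi]
            seg[seg == -1] = -3

    family_bp = {fam: 0 for fam in REPEAT_FAMILIES}
    simple_bp = 0
    low_bp = 0
    masked_records = []
    for rec in seqs:
        arr = claims[rec.id]
        for idx, fam in enumerate(REPEAT_FAMILIES):
            family_bp[fam] += int((arr == idx).sum())
        simple_bp += int((arr == -2).sum())
        low_bp += int((arr == -3).sum())
        chars = np.frombuffer(rec.seq.encode(), dtype=np.uint8).copy()
        lower = arr != -1
        is_upper = (chars >= 65) & (chars <= 90)
        chars[lower & is_upper] += 32
        masked_records.append(replace(rec, seq=chars.tobytes().decode()))
    summary = RepeatSummary(
        family_bp=family_bp,
        simple_repeats_bp=simple_bp,
        low_complexity_bp=low_bp,
        total_sequence_bp=total_bp,
    )
    return SeqRecordSet(masked_records), summary


def low_complexity_windows(
    seq: str, window: int = 64, threshold: float = 1.5
) -> list[tuple[int, int]]:
    """Merged intervals of windows with Shannon entropy below threshold."""
    s = seq.upper()
    n = len(s)
    if n < window:
        return []
    step = window // 2
    flagged = []
    for lo in range(0, n - window + 1, step):
        win = s[lo: lo + window]
        counts = Counter(b for b in win if b in "ACGT")
        total = sum(counts.values())
        if total < window // 2:
            continue
        h = -sum((c / total) * log2(c / total) for c in counts.values())
        if h < threshold:
            flagged.append((lo, lo + window))
    merged: list[tuple[int, int]] = []
    for lo, hi in flagged:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    return merged


# ---------------------------------------------------------------------------
# SSRs


@dataclass(frozen=True)
class SsrLocus:
    seq_id: str
    motif: str  # canonical: minimal rotation over both strands
    copy_number: float
    start: int
    end: int
    left_flank: str = ""
    right_flank: str = ""
    left_truncated: bool = False
    right_truncated: bool = False

    def length(self) -> int:
        return self.end - self.start


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation over the motif and its reverse complement."""
    rot = [motif[i:] + motif[:i] for i in range(len(motif))]
    rc = revcomp(motif)
    rot += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(rot)


def is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def enumerate_tandem_runs(
    seq: str, min_copies: dict[int, int] | None = None
) -> list[tuple[int, int, int]]:
    """All maximal perfect tandem runs meeting the per-motif-length copy minima.

    Returns (start, end, motif_length) triples, 0-based half-open, including
    partial trailing motif copies in the run.
    """
    min_copies = min_copies or DEFAULT_MIN_COPIES
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    acgt = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    runs = []
    for m, need in sorted(min_copies.items()):
        if n < 2 * m:
            continue
        eq = (arr[:-m] == arr[m:]) & acgt[:-m] & acgt[m:]
        i = 0
        while i < len(eq):
            if not eq[i]:
                i += 1
                continue
            j = i
            while j < len(eq) and eq[j]:
                j += 1
            run_len = (j - i) + m  # total tandem interval length
            if run_len / m >= need and is_primitive(s[i: i + m]):
                runs.append((i, i + run_len, m))
            i = j
    return runs


def detect_ssrs(
    seqs: SeqRecordSet,
    min_copies: dict[int, int] | None = None,
    flank_len: int = 200,
) -> list[SsrLocus]:
    """Perfect SSRs as maximal tandem runs, overlap-resolved.

    Overlapping candidates keep the longest run, then the shortest motif,
    then the leftmost start.  Flanks are extracted from the input sequence
    and flagged when truncated by a sequence end.
    """
    loci: list[SsrLocus] = []
    for rec in seqs:
        runs = enumerate_tandem_runs(rec.seq, min_copies)
        runs.sort(key=lambda r: (-(r[1] - r[0]), r[2], r[0]))
        claimed = np.zeros(len(rec.seq), dtype=bool)
        for start, end, m in runs:
            if claimed[start:end].any():
                continue
            claimed[start:end] = True
            lf_start = max(0, start - flank_len)
            rf_end = min(len(rec.seq), end + flank_len)
            loci.append(
                SsrLocus(
                    seq_id=rec.id,
                    motif=canonical_motif(rec.seq[start: start + m].upper()),
                    copy_number=(end - start) / m,
                    start=start,
                    end=end,
                    left_flank=rec.seq[lf_start:start],
                    right_flank=rec.seq[end:rf_end],
                    left_truncated=start - flank_len < 0,
                    right_truncated=end + flank_len > len(rec.seq),
                )
            )
    loci.sort(key=lambda x: (x.seq_id, x.start))
    return loci


def ssr_table(loci: list[SsrLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seq_id": x.seq_id,
                "motif": x.motif,
                "copy_number": round(x.copy_number, 2),
                "start": x.start,
                "end": x.end,
                "left_flank": x.left_flank,
                "right_flank": x.right_flank,
                "left_truncated": x.left_truncated,
                "right_truncated": x.right_truncated,
            }
            for x in loci
        ]
    )
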