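"""Assign pooled shotgun reads back to individual clones.

Clones are arrayed on an (n_rows x n_cols) grid and sequenced as row pools
and column pools.  A read sequenced in a row pool must come from one clone
of that row; which column it belongs to is decided by shared-sequence
evidence: the read is assigned to column c iff it shares at least
``min_shared`` canonical minimizers with the reads of exactly one column
pool c (and symmetrically for column-pool reads).  Reads supported by
several opposite-axis pools are flagged ambiguous and excluded from the
per-clone bins; reads supported by none are unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


@dataclass(frozen=True)
class Grid:
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def n_pools(self) -> int:
        return self.n_rows + self.n_cols

    def cell_of(self, clone_index: int) -> tuple[int, int]:
        """Row-major cell of the clone with the given 0-based index."""
        if clone_index >= self.n_rows * self.n_cols:
            raise ValueError("clone index outside grid")
        return divmod(clone_index, self.n_cols)


@dataclass
class PooledReadSet:
    pool_id: str
    axis: str  # "row" or "col"
    index: int
    reads: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.axis not in ("row", "col"):
            raise ValueError(f"axis must be 'row' or 'col', got {self.axis!r}")


@dataclass
class DeconvolutionResult:
    """Partition of all pooled reads into assigned / ambiguous / unassigned."""

    assignments: dict[str, tuple[int, int]] = field(default_factory=dict)
    ambiguous: dict[str, frozenset] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)
    bins: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    def categories_partition(self, all_read_ids: set[str]) -> bool:
        a, b, c = set(self.assignments), set(self.ambiguous), self.unassigned
        return (a | b | c) == all_read_ids and not (a & b or a & c or b & c)


def canonical_minimizers(seq: str, k: int = 21, w: int = 11) -> set[int]:
    """Strand-symmetric minimizer set of a sequence.

    The minimizer of each window of ``w`` consecutive k-mers is the smallest
    canonical k-mer code (the smaller of a k-mer's code and its reverse
    complement's), so a read and its reverse complement yield identical sets.
    """
    enc = _ENC[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    n = len(enc) - k + 1
    if n <= 0:
        return set()
    valid = enc != 255
    e = np.where(valid, enc, 0).astype(np.int64)
    fwd = np.zeros(n, dtype=np.int64)
    for j in range(k):
        fwd = (fwd << 2) | e[j: j + n]
    e_rc = (3 - e)[::-1]
    rc = np.zeros(n, dtype=np.int64)
    for j in range(k):
        rc = (rc << 2) | e_rc[j: j + n]
    canon = np.minimum(fwd, rc[::-1])
    if not valid.all():
        bad = ~valid
        cs = np.concatenate([[0], np.cumsum(bad)])
        ok = (cs[k:] - cs[:-k]) == 0
        canon = np.where(ok, canon, np.iinfo(np.int64).max)
    if n < w:
        windows = canon.reshape(1, -1)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(canon, w)
    mins = windows.min(axis=1)
    out = set(int(x) for x in np.unique(mins))
    out.discard(np.iinfo(np.int64).max)
    return out


def build_minimizer_index(
    pool: PooledReadSet, k: int = 21, w: int = 11
) -> dict[int, set[str]]:
    """Map each canonical minimizer to the pool reads containing it."""
    index: dict[int, set[str]] = {}
    for read_id, seq in pool.reads:
        mins = canonical_minimizers(seq, k, w)
        if not mins:
            warnings.warn(f"read {read_id} shorter than k={k}; no minimizers")
        for m in mins:
            index.setdefault(m, set()).add(read_id)
    return index


def _check_pools(pools: list[PooledReadSet], grid: Grid) -> None:
    rows = sorted(p.index for p in pools if p.axis == "row")
    cols = sorted(p.index for p in pools if p.axis == "col")
    if rows != list(range(grid.n_rows)) or cols != list(range(grid.n_cols)):
        raise ValueError(
            f"pools do not cover the {grid.n_rows}x{grid.n_cols} grid axes: "
            f"rows {rows}, cols {cols}"
        )
    seen: set[str] = set()
    for p in pools:
        for read_id, _ in p.reads:
            if read_id in seen:
                raise ValueError(f"read id {read_id!r} appears in two pools")
            seen.add(read_id)


def deconvolve(
    pools: list[PooledReadSet],
    grid: Grid,
    k: int = 21,
    w: int = 11,
    min_shared: int = 3,
) -> DeconvolutionResult:
    """Row/column intersection of pooled reads by shared minimizer evidence."""
    _check_pools(pools, grid)
    # minimizer -> bitmask over pools (rows then cols)
    pool_bit: dict[str, int] = {}
    ordered = sorted(pools, key=lambda p: (p.axis != "row", p.index))
    for bit, p in enumerate(ordered):
        pool_bit[p.pool_id] = bit
    mask_of: dict[int, int] = {}
    read_minimizers: dict[str, set[int]] = {}
    for p in ordered:
        bit = pool_bit[p.pool_id]
        for read_id, seq in p.reads:
            mins = canonical_minimizers(seq, k, w)
            read_minimizers[read_id] = mins
            for m in mins:
                mask_of[m] = mask_of.get(m, 0) | (1 << bit)

    result = DeconvolutionResult()
    n_rows = grid.n_rows
    for p in ordered:
        own_axis_is_row = p.axis == "row"
        opp_range = (
            range(n_rows, n_rows + grid.n_cols) if own_axis_is_row else range(n_rows)
        )
        for read_id, _seq in p.reads:
            counts = dict.fromkeys(opp_range, 0)
            for m in read_minimizers[read_id]:
                mask = mask_of.get(m, 0)
                for b in opp_range:
                    if mask >> b & 1:
                        counts[b] += 1
            supported = [b for b in opp_range if counts[b] >= min_shared]
            if len(supported) == 1:
                b = supported[0]
                cell = (
                    (p.index, b - n_rows) if own_axis_is_row else (b, p.index)
                )
                result.assignments[read_id] = cell
                result.bins.setdefault(cell, []).append(read_id)
            elif len(supported) > 1:
                cells = frozenset(
                    (p.index, b - n_rows) if own_axis_is_row else (b, p.index)
                    for b in supported
                )
                result.ambiguous[read_id] = cells
            else:
                result.unassigned.add(read_id)
    for cell in result.bins:
        result.bins[cell].sort()
    return result
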