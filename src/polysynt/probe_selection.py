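"""Screening of hybridization probes and candidate clones.

Reproduces the clone-selection funnel: keep probes with exactly one
template hit of sufficient identical length ("single copy" probes), keep
those whose hybridization count on the polyploid library falls in a copy
band compatible with the expected homolog number, then select clones hit by
at least two retained probes that map close together on the template.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class SelectionParams:
    min_identical: int = 35  # bp of identical probe/template sequence
    copy_min: int = 4  # inclusive band of clone hits on the polyploid library
    copy_max: int = 20
    max_pair_distance: int = 50_000  # bp between probe positions on the template
    one_clone_per_region: bool = False

    def __post_init__(self) -> None:
        if self.min_identical <= 0:
            raise ValueError("min_identical must be positive")
        if self.copy_min > self.copy_max:
            raise ValueError("copy band low > high")


@dataclass
class ProbeHitTable:
    """Probe-to-template BLAST-style hits and probe-to-clone hybridization hits.

    ``template_hits`` columns: probe_id, chrom, position, identical_length.
    ``polyploid_counts`` columns: probe_id, clone_id (one row per hit).
    """

    template_hits: pd.DataFrame
    polyploid_counts: pd.DataFrame

    def validate(self, chrom_lengths: dict[str, int] | None = None) -> None:
        th = self.template_hits
        if (th["identical_length"] < 0).any():
            raise ValueError("negative identical_length")
        if chrom_lengths is not None:
            for _, row in th.iterrows():
                if row["position"] >= chrom_lengths.get(row["chrom"], 0):
                    raise ValueError(
                        f"probe {row['probe_id']} position outside template"
                    )


def filter_single_copy(table: ProbeHitTable, params: SelectionParams) -> list[str]:
    """Probes with exactly one template hit of identical_length >= threshold."""
    th = table.template_hits
    if th.empty:
        return []
    counts = th.groupby("probe_id").size()
    single = counts[counts == 1].index
    strong = th[
        th["probe_id"].isin(single) & (th["identical_length"] >= params.min_identical)
    ]
    return sorted(strong["probe_id"].unique())


def filter_copy_number(
    probe_ids: list[str], table: ProbeHitTable, params: SelectionParams
) -> list[str]:
    """Retain probes whose polyploid clone-hit count lies in the copy band."""
    if not probe_ids:
        return []
    pc = table.polyploid_counts
    counts = pc[pc["probe_id"].isin(probe_ids)].groupby("probe_id").size()
    kept = [
        p
        for p in probe_ids
        if params.copy_min <= counts.get(p, 0) <= params.copy_max
    ]
    return sorted(kept)


def select_candidate_clones(
    probe_ids: list[str], table: ProbeHitTable, params: SelectionParams
) -> pd.DataFrame:
    """Clones supported by >= 2 retained probes mapping close on the template.

    Returns columns (clone_id, probe_a, probe_b, template_distance), one row
    per clone with its best supporting probe pair.  With
    ``one_clone_per_region`` set, overlapping template windows keep a single
    clone, tie-broken by probe support, then smaller pair distance, then
    clone id.
    """
    cols = ["clone_id", "probe_a", "probe_b", "template_distance"]
    if not probe_ids:
        return pd.DataFrame(columns=cols)
    pos = (
        table.template_hits[table.template_hits["probe_id"].isin(probe_ids)]
        .set_index("probe_id")[["chrom", "position"]]
        .to_dict("index")
    )
    pc = table.polyploid_counts
    by_clone = pc[pc["probe_id"].isin(probe_ids)].groupby("clone_id")["probe_id"]
    rows = []
    for clone_id, probes in sorted(by_clone):
        probes = sorted(set(probes) & set(pos))
        best = None
        for i in range(len(probes)):
            for j in range(i + 1, len(probes)):
                a, b = probes[i], probes[j]
                if pos[a]["chrom"] != pos[b]["chrom"]:
                    continue
                dist = abs(pos[a]["position"] - pos[b]["position"])
                if dist <= params.max_pair_distance and (
                    best is None or dist < best[2]
                ):
                    best = (a, b, dist)
        if best is not None:
            rows.append(
                {
                    "clone_id": clone_id,
                    "probe_a": best[0],
                    "probe_b": best[1],
                    "template_distance": best[2],
                    "_support": len(probes),
                    "_chrom": pos[best[0]]["chrom"],
                    "_pos": min(pos[best[0]]["position"], pos[best[1]]["position"]),
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    if params.one_clone_per_region:
        df = df.sort_values(
            ["_support", "template_distance", "clone_id"],
            ascending=[False, True, True],
        )
        kept = []
        windows: list[tuple[str, int, int]] = []  # (chrom, lo, hi)
        for _, row in df.iterrows():
            lo = row["_pos"]
            hi = row["_pos"] + row["template_distance"]
            overlapping = any(
                c == row["_chrom"] and lo <= whi and wlo <= hi
                for c, wlo, whi in windows
            )
            if not overlapping:
                kept.append(row)
                windows.append((row["_chrom"], lo, hi))
        df = pd.DataFrame(kept)
    df = df.sort_values("clone_id").reset_index(drop=True)
    return df[cols]
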