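"""Readers and writers for the on-disk formats the pipeline touches.

Conventions
-----------
All in-memory coordinates are 0-based half-open.  On-disk formats use their
own standards (GFF3 and AGP are 1-based inclusive); the converters here are
exact inverses of each other.  Strand "-" features are stored on forward
coordinates with a strand flag and are never reverse-complemented at parse
time.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Malformed or contract-violating on-disk input."""


class ContractError(ValueError):
    """A precondition of an operation was violated by the caller."""


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class SeqRecord:
    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SeqRecordSet:
    """An ordered set of uniquely named DNA records."""

    records: list[SeqRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            if not rec.seq:
                raise FormatError(f"empty sequence for id {rec.id!r}")
            bad = set(rec.seq.upper()) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"non-IUPAC-DNA characters {sorted(bad)} in record {rec.id!r}"
                )

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> SeqRecord:
        for rec in self.records:
            if rec.id == seq_id:
                return rec
        raise KeyError(seq_id)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def add(self, rec: SeqRecord) -> None:
        self.records.append(rec)
        self.validate()

    def upper(self) -> "SeqRecordSet":
        return SeqRecordSet([replace(r, seq=r.seq.upper()) for r in self.records])


def read_fasta(path, keep_case: bool = False) -> SeqRecordSet:
    """Read a FASTA file into a SeqRecordSet.

    Sequences are uppercased unless ``keep_case`` is set (soft-masked input).
    Duplicate ids, empty sequences and non-DNA characters raise FormatError.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not keep_case:
            seq = seq.upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc))
    return SeqRecordSet(records)


def write_fasta(recset: SeqRecordSet, path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in recset
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# features (GFF3)


@dataclass(frozen=True)
class Feature:
    """One annotated interval; ``start``/``end`` are 0-based half-open."""

    seq_id: str
    source: str
    type: str
    start: int
    end: int
    strand: str = "."
    attributes: tuple = ()  # tuple of (key, value) pairs, order-preserving

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"inverted/empty interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in "+-.":
            raise FormatError(f"bad strand {self.strand!r}")

    @property
    def attr(self) -> dict:
        return dict(self.attributes)

    def length(self) -> int:
        return self.end - self.start


@dataclass
class FeatureTable:
    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, ftype: str) -> "FeatureTable":
        return FeatureTable([f for f in self.features if f.type == ftype])

    def on(self, seq_id: str) -> "FeatureTable":
        return FeatureTable([f for f in self.features if f.seq_id == seq_id])

    def sorted(self) -> "FeatureTable":
        return FeatureTable(
            sorted(self.features, key=lambda f: (f.seq_id, f.start, f.end, f.type))
        )

    def validate_against(self, seqs: SeqRecordSet) -> None:
        lengths = {r.id: len(r.seq) for r in seqs}
        for f in self.features:
            if f.seq_id not in lengths:
                raise FormatError(f"feature on unknown sequence {f.seq_id!r}")
            if f.end > lengths[f.seq_id]:
                raise FormatError(
                    f"feature [{f.start},{f.end}) exceeds {f.seq_id} length"
                )


_GFF3_ESCAPE_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "=;,&%\t"
)


def _esc(value: str) -> str:
    return urllib.parse.quote(str(value), safe=_GFF3_ESCAPE_SAFE + " ")


def _unesc(value: str) -> str:
    return urllib.parse.unquote(value)


def read_gff3(path) -> FeatureTable:
    features = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"GFF3 line has {len(cols)} columns: {line!r}")
            seq_id, source, ftype, start, end, _score, strand, _phase, attrs = cols
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise FormatError(f"GFF3 start > end on line: {line!r}")
            pairs = []
            if attrs not in (".", ""):
                for item in attrs.split(";"):
                    if not item:
                        continue
                    key, _, val = item.partition("=")
                    pairs.append((_unesc(key), _unesc(val)))
            features.append(
                Feature(
                    seq_id=seq_id,
                    source=source,
                    type=ftype,
                    start=start_i - 1,  # 1-based inclusive -> 0-based half-open
                    end=end_i,
                    strand=strand,
                    attributes=tuple(pairs),
                )
            )
    return FeatureTable(features)


def write_gff3(table: FeatureTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in table:
            attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in f.attributes) or "."
            fh.write(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# AGP v2.1 layouts


@dataclass(frozen=True)
class AgpRow:
    """One AGP v2.1 row; object/component coordinates 0-based half-open."""

    object_id: str
    object_start: int
    object_end: int
    part_number: int
    component_type: str  # "W" contig, "N" gap
    component_id: str = ""  # W rows
    component_start: int = 0
    component_end: int = 0
    orientation: str = "+"
    gap_length: int = 0  # N rows
    gap_kind: str = "scaffold"
    comment: str = ""


def write_agp(rows: list[AgpRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for r in rows:
            if r.component_type == "W":
                cols = [
                    r.object_id,
                    str(r.object_start + 1),
                    str(r.object_end),
                    str(r.part_number),
                    "W",
                    r.component_id,
                    str(r.component_start + 1),
                    str(r.component_end),
                    r.orientation,
                ]
            elif r.component_type == "N":
                cols = [
                    r.object_id,
                    str(r.object_start + 1),
                    str(r.object_end),
                    str(r.part_number),
                    "N",
                    str(r.gap_length),
                    r.gap_kind,
                    "yes",
                    "align_genus",
                ]
            else:
                raise FormatError(f"unsupported component type {r.component_type!r}")
            line = "\t".join(cols)
            if r.comment:
                line += f"\t# {r.comment}"
            fh.write(line + "\n")


def read_agp(path) -> list[AgpRow]:
    rows: list[AgpRow] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            comment = ""
            if "\t# " in line:
                line, comment = line.split("\t# ", 1)
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"AGP row has {len(cols)} columns: {line!r}")
            ctype = cols[4]
            common = dict(
                object_id=cols[0],
                object_start=int(cols[1]) - 1,
                object_end=int(cols[2]),
                part_number=int(cols[3]),
                component_type=ctype,
                comment=comment,
            )
            if ctype == "W":
                rows.append(
                    AgpRow(
                        component_id=cols[5],
                        component_start=int(cols[6]) - 1,
                        component_end=int(cols[7]),
                        orientation=cols[8],
                        **common,
                    )
                )
            elif ctype == "N":
                rows.append(AgpRow(gap_length=int(cols[5]), gap_kind=cols[6], **common))
            else:
                raise FormatError(f"unsupported AGP component type {ctype!r}")
    _check_tiling(rows)
    return rows


def _check_tiling(rows: list[AgpRow]) -> None:
    by_obj: dict[str, list[AgpRow]] = {}
    for r in rows:
        by_obj.setdefault(r.object_id, []).append(r)
    for obj, obj_rows in by_obj.items():
        pos = 0
        for part, r in enumerate(obj_rows, start=1):
            if r.part_number != part:
                raise FormatError(f"{obj}: part numbers not consecutive")
            if r.object_start != pos:
                raise FormatError(f"{obj}: parts do not tile the object contiguously")
            pos = r.object_end


def layout_to_agp_rows(layout, contig_lengths: dict[str, int]) -> list[AgpRow]:
    """Serialize an ordered contig layout as AGP v2.1 rows.

    ``layout`` must expose ``clone_id``, a truthy ``validated`` flag and
    ``placed`` entries with ``contig_id``, ``orientation`` and
    ``estimated_gap_after`` (template-projected gap in bp, possibly negative,
    ``None`` after the last contig).  Negative gap estimates become 1-bp "N"
    rows flagged ``overlap_suspected`` in a trailing comment.
    """
    if not getattr(layout, "validated", False):
        raise ContractError("layout must be validated before serialization")
    rows: list[AgpRow] = []
    pos = 0
    part = 0
    placed = list(layout.placed)
    for i, p in enumerate(placed):
        clen = contig_lengths[p.contig_id]
        part += 1
        rows.append(
            AgpRow(
                object_id=layout.clone_id,
                object_start=pos,
                object_end=pos + clen,
                part_number=part,
                component_type="W",
                component_id=p.contig_id,
                component_start=0,
                component_end=clen,
                orientation=p.orientation,
            )
        )
        pos += clen
        gap = p.estimated_gap_after
        if i < len(placed) - 1 and gap is not None:
            part += 1
            if gap < 0:
                rows.append(
                    AgpRow(
                        object_id=layout.clone_id,
                        object_start=pos,
                        object_end=pos + 1,
                        part_number=part,
                        component_type="N",
                        gap_length=1,
                        gap_kind="scaffold",
                        comment="gap_kind=overlap_suspected",
                    )
                )
                pos += 1
            else:
                glen = max(int(gap), 1)
                rows.append(
                    AgpRow(
                        object_id=layout.clone_id,
                        object_start=pos,
                        object_end=pos + glen,
                        part_number=part,
                        component_type="N",
                        gap_length=glen,
                        gap_kind="scaffold",
                    )
                )
                pos += glen
    return rows


def write_layout_agp(layout, contig_lengths: dict[str, int], path) -> None:
    write_agp(layout_to_agp_rows(layout, contig_lengths), path)


# ---------------------------------------------------------------------------
# TSV reports


def write_tsv_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def format_pct(x: float) -> str:
    """Percentages are reported to one decimal place, e.g. '78.2%'."""
    return f"{x:.1f}%"
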