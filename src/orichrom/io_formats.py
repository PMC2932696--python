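"""Readers and writers for the external tables the pipeline touches.

All on-disk genomic coordinates are 1-based inclusive, except BED exports
(0-based half-open). Missing values are spelled ``NA`` on disk. Every
reader accepts plain or gzip-compressed files.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ProbeTrack",
    "AcsAnnotation",
    "DinucleotidePropertyTable",
    "FeatureRecord",
    "TimingRecord",
    "DINUCLEOTIDES",
    "FEATURE_KINDS",
    "read_probe_track",
    "write_probe_track",
    "read_acs_table",
    "write_acs_table",
    "read_property_table",
    "write_property_table",
    "read_feature_table",
    "write_feature_table",
    "read_timing_table",
    "write_timing_table",
    "read_fasta",
    "write_fasta",
    "write_calls_bed",
]

#: The 16 dinucleotides in lexicographic order — the canonical column order
#: of property tables.
DINUCLEOTIDES = tuple(a + b for a in "ACGT" for b in "ACGT")

#: Closed set of genomic feature kinds the context analysis understands.
FEATURE_KINDS = frozenset(
    {"TSS", "gene_end", "telomere", "centromere_CDEII", "ARS_interval"}
)


class FormatError(ValueError):
    """A file did not conform to the expected tabular layout."""


def _open_text(path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ProbeTrack:
    """Per-chromosome tiling-array track of log2 occupancy ratios.

    Coordinates are 1-based and strictly increasing; nominal spacing is
    4 bp but gaps are permitted.  ``dup_flags[i]`` is True when the probe
    sequence occurs elsewhere on the array.
    """

    chrom: str
    coords: np.ndarray  # int, strictly increasing
    values: np.ndarray  # float, NaN = missing
    dup_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.dup_flags is None:
            self.dup_flags = np.zeros(self.coords.shape, dtype=bool)
        self.dup_flags = np.asarray(self.dup_flags, dtype=bool)
        if np.any(np.diff(self.coords) <= 0):
            bad = int(self.coords[np.argmax(np.diff(self.coords) <= 0) + 1])
            raise FormatError(
                f"{self.chrom}: coordinates not strictly increasing near {bad}"
            )

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class AcsAnnotation:
    """One origin's 15-bp proACS anchor.

    ``acs_start`` is the minimum of the proACS start/end coordinates;
    ``t_rich_strand`` is 'W' when the ACS reads T-rich 5'→3' on the Watson
    strand and 'C' otherwise.
    """

    origin_id: str
    chrom: str
    acs_start: int
    t_rich_strand: str
    source: str = "curated"

    def __post_init__(self) -> None:
        if self.t_rich_strand not in ("W", "C"):
            raise FormatError(
                f"{self.origin_id}: unknown strand {self.t_rich_strand!r}"
            )
        if self.acs_start < 1:
            raise FormatError(f"{self.origin_id}: acs_start {self.acs_start} < 1")

    @property
    def orientation(self) -> int:
        """+1 for Watson T-rich strand, −1 for Crick."""
        return 1 if self.t_rich_strand == "W" else -1


@dataclass
class DinucleotidePropertyTable:
    """One DiProDB-style property: a value for each of the 16 dinucleotides."""

    property_id: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(DINUCLEOTIDES):
            raise FormatError(
                f"property {self.property_id!r}: expected exactly the 16 "
                f"dinucleotides, got {len(self.values)} entries"
            )
        for dn, v in self.values.items():
            if not math.isfinite(v):
                raise FormatError(f"property {self.property_id!r}: {dn} not finite")

    def as_array(self) -> np.ndarray:
        """Values in canonical ``DINUCLEOTIDES`` order."""
        return np.array([self.values[dn] for dn in DINUCLEOTIDES], dtype=float)


@dataclass
class FeatureRecord:
    kind: str
    chrom: str
    coord: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.kind!r}")
        if self.coord < 1:
            raise FormatError(f"feature coordinate {self.coord} < 1")


@dataclass
class TimingRecord:
    """Replication timing of one origin: HU-earliness flag and optional Trep."""

    origin_id: str
    early: bool
    trep: float | None = None

    def __post_init__(self) -> None:
        if self.trep is not None and not (self.trep >= 0):
            raise FormatError(f"{self.origin_id}: trep must be >= 0")


# ---------------------------------------------------------------------------
# Probe tracks
# ---------------------------------------------------------------------------


def _parse_value(tok: str) -> float:
    try:
        return float(tok)
    except ValueError:
        return float("nan")


def read_probe_track(path) -> dict[str, ProbeTrack]:
    """Read a tab-delimited chrom/coordinate/value[/dup] track.

    A header line is detected by a non-numeric coordinate field and
    skipped. Unparseable values become NaN; a non-numeric coordinate on a
    data line, or a duplicated coordinate within a chromosome, raises
    :class:`FormatError` naming the offending line/coordinate.
    """
    per_chrom: dict[str, list[tuple[int, float, bool]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom, coord_tok, value_tok = fields[0], fields[1], fields[2]
            try:
                coord = int(coord_tok)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate {coord_tok!r}"
                ) from None
            dup = False
            if len(fields) >= 4 and fields[3] not in ("", "NA"):
                dup = fields[3] in ("1", "True", "TRUE", "true")
            per_chrom.setdefault(chrom, []).append(
                (coord, _parse_value(value_tok), dup)
            )

    tracks: dict[str, ProbeTrack] = {}
    for chrom, rows in per_chrom.items():
        rows.sort(key=lambda r: r[0])
        coords = np.array([r[0] for r in rows], dtype=np.int64)
        dup_coords = coords[:-1][np.diff(coords) == 0]
        if dup_coords.size:
            raise FormatError(
                f"{path}: duplicated coordinate {int(dup_coords[0])} on {chrom}"
            )
        tracks[chrom] = ProbeTrack(
            chrom=chrom,
            coords=coords,
            values=np.array([r[1] for r in rows]),
            dup_flags=np.array([r[2] for r in rows], dtype=bool),
        )
    return tracks


def write_probe_track(tracks: Mapping[str, ProbeTrack], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("chrom\tcoord\tvalue\tdup\n")
        for chrom in sorted(tracks):
            t = tracks[chrom]
            for c, v, d in zip(t.coords, t.values, t.dup_flags):
                val = "NA" if not math.isfinite(v) else repr(float(v))
                fh.write(f"{chrom}\t{int(c)}\t{val}\t{int(d)}\n")


# ---------------------------------------------------------------------------
# ACS tables
# ---------------------------------------------------------------------------

_ACS_HEADER = ("origin_id", "chrom", "acs_start", "t_rich_strand", "source")


def read_acs_table(path) -> list[AcsAnnotation]:
    """Read an origin table (origin id, chrom, ACS coordinate, T-rich strand,
    source), preserving input order."""
    out: list[AcsAnnotation] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == _ACS_HEADER[0]:
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected >=4 columns")
            source = fields[4] if len(fields) > 4 else "curated"
            try:
                start = int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate {fields[2]!r}"
                ) from None
            try:
                out.append(
                    AcsAnnotation(fields[0], fields[1], start, fields[3], source)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_acs_table(acs_list: Iterable[AcsAnnotation], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(_ACS_HEADER) + "\n")
        for a in acs_list:
            fh.write(
                f"{a.origin_id}\t{a.chrom}\t{a.acs_start}\t"
                f"{a.t_rich_strand}\t{a.source}\n"
            )


# ---------------------------------------------------------------------------
# Dinucleotide property tables (DiProDB layout)
# ---------------------------------------------------------------------------


def read_property_table(path) -> list[DinucleotidePropertyTable]:
    """Read a table of one row per property with 16 dinucleotide values.

    The column order is taken from the header when present (fields that
    look like dinucleotides), otherwise the canonical lexicographic order
    is assumed.  A row with a value count other than 16 is an error.
    """
    order = list(DINUCLEOTIDES)
    out: list[DinucleotidePropertyTable] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            tail = fields[1:]
            if lineno == 1 and all(f.upper() in DINUCLEOTIDES for f in tail):
                if len(tail) != 16:
                    raise FormatError(f"{path}:1: header must list 16 dinucleotides")
                order = [f.upper() for f in tail]
                continue
            if len(tail) != 16:
                raise FormatError(
                    f"{path}:{lineno}: property {fields[0]!r} has "
                    f"{len(tail)} values, expected 16"
                )
            try:
                vals = {dn: float(tok) for dn, tok in zip(order, tail)}
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value") from None
            out.append(DinucleotidePropertyTable(fields[0], vals))
    return out


def write_property_table(tables: Iterable[DinucleotidePropertyTable], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("property_id\t" + "\t".join(DINUCLEOTIDES) + "\n")
        for t in tables:
            vals = "\t".join(repr(float(t.values[dn])) for dn in DINUCLEOTIDES)
            fh.write(f"{t.property_id}\t{vals}\n")


# ---------------------------------------------------------------------------
# Feature and timing tables
# ---------------------------------------------------------------------------


def read_feature_table(path) -> list[FeatureRecord]:
    out: list[FeatureRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "kind":
                continue
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            strand = fields[3] if len(fields) > 3 else "."
            try:
                coord = int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate {fields[2]!r}"
                ) from None
            try:
                out.append(FeatureRecord(fields[0], fields[1], coord, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return out


def write_feature_table(features: Iterable[FeatureRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("kind\tchrom\tcoord\tstrand\n")
        for f in features:
            fh.write(f"{f.kind}\t{f.chrom}\t{f.coord}\t{f.strand}\n")


def read_timing_table(path) -> list[TimingRecord]:
    out: list[TimingRecord] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "origin_id":
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 columns")
            if fields[1] not in ("0", "1"):
                raise FormatError(
                    f"{path}:{lineno}: early flag must be 0/1, got {fields[1]!r}"
                )
            trep: float | None = None
            if len(fields) > 2 and fields[2] not in ("", "NA"):
                trep = float(fields[2])
            out.append(TimingRecord(fields[0], fields[1] == "1", trep))
    return out


def write_timing_table(records: Iterable[TimingRecord], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("origin_id\tearly\ttrep\n")
        for r in records:
            trep = "NA" if r.trep is None else repr(float(r.trep))
            fh.write(f"{r.origin_id}\t{int(r.early)}\t{trep}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a {chrom: uppercase sequence} mapping."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED export of nucleosome calls
# ---------------------------------------------------------------------------


def write_calls_bed(callsets, acs_map: Mapping[str, AcsAnnotation], path) -> int:
    """Write nucleosome midpoint calls as BED6 intervals (midpoint ±73 bp).

    Relative midpoints are mapped to genomic coordinates through each
    origin's ACS anchor and orientation; a call set whose origin is absent
    from ``acs_map`` is skipped.  Returns the number of skipped call sets.

    The score column is the template correlation × 1000, rounded.
    """
    skipped = 0
    with _open_text(path, "wt") as fh:
        fh.write('track name=nucleosome_calls description="nucleosome midpoints"\n')
        for cs in callsets:
            acs = acs_map.get(cs.origin_id)
            if acs is None:
                skipped += 1
                continue
            strand = "+" if acs.orientation == 1 else "-"
            for mid, score, label in zip(cs.midpoints, cs.scores, cs.labels):
                g = acs.acs_start + acs.orientation * int(mid)
                fh.write(
                    f"{acs.chrom}\t{g - 74}\t{g + 74}\t"
                    f"{cs.origin_id}:{label:+d}\t{round(score * 1000)}\t{strand}\n"
                )
    if skipped:
        import warnings

        warnings.warn(f"write_calls_bed: {skipped} call set(s) without ACS mapping")
    return skipped
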