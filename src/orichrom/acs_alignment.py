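"""Curation of the ACS origin list and construction of the ACS-aligned,
T-rich-oriented occupancy matrix.

The alignment anchor is the T residue at position 1 of the 15-bp proACS.
Relative position 0 is the probe nearest ``acs_start`` (ties broken toward
the lower genomic coordinate); positive positions point toward the B1
element, i.e. 3' on the T-rich strand, for every origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AcsAnnotation, ProbeTrack

__all__ = [
    "AcsNotFoundError",
    "AlignedMatrix",
    "revcomp",
    "locate_acs",
    "sgd_acs_to_15bp",
    "merge_and_dedup",
    "filter_origins",
    "filter_missing_calls",
    "build_aligned_matrix",
    "reflect_matrix",
]

PROACS_LEN = 15

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class AcsNotFoundError(ValueError):
    """A proACS sequence could not be located in the genome."""

    def __init__(self, origin_id: str | None, message: str):
        self.origin_id = origin_id
        super().__init__(message)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All 1-based start coordinates of ``needle`` in ``haystack``."""
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i + 1)
        start = i + 1


def locate_acs(
    genome: dict[str, str],
    chrom: str,
    proacs_seq: str,
    described_coord: int,
    origin_id: str | None = None,
) -> tuple[int, str]:
    """Locate a 15-bp proACS on a chromosome.

    Both strands are searched (a Crick-strand hit means the T-rich strand
    is 'C').  When several matches exist, the match closest to the
    previously described coordinate is chosen; a tie prefers the lower
    coordinate.  Returns ``(acs_start, t_rich_strand)``.
    """
    if len(proacs_seq) != PROACS_LEN:
        raise ValueError(f"proACS must be {PROACS_LEN} bp, got {len(proacs_seq)}")
    seq = genome[chrom].upper()
    motif = proacs_seq.upper()
    hits = [(pos, "W") for pos in _find_all(seq, motif)]
    rc = revcomp(motif)
    if rc != motif:
        hits += [(pos, "C") for pos in _find_all(seq, rc)]
    if not hits:
        raise AcsNotFoundError(
            origin_id, f"proACS {proacs_seq!r} not found on {chrom}"
            + (f" (origin {origin_id})" if origin_id else "")
        )
    hits.sort(key=lambda h: (abs(h[0] - described_coord), h[0]))
    return hits[0]


def sgd_acs_to_15bp(start: int, end: int) -> int:
    """Convert an 11-bp SGD ACS call to the 15-bp proACS start coordinate.

    The proACS start is the minimum of the call's start/end minus 2.
    """
    out = min(start, end) - 2
    if out < 1:
        raise ValueError(f"15-bp proACS start {out} falls before the chromosome")
    return out


def merge_and_dedup(
    curated: list[AcsAnnotation],
    sgd: list[AcsAnnotation],
    tol_bp: int = 50,
) -> list[AcsAnnotation]:
    """Union of curated and SGD origin calls with near-duplicates removed.

    An SGD entry within ``tol_bp`` of a curated entry on the same
    chromosome duplicates it and is dropped; the curated entry is kept.
    """
    out = list(curated)
    for s in sgd:
        dup = any(
            c.chrom == s.chrom and abs(c.acs_start - s.acs_start) <= tol_bp
            for c in curated
        )
        if not dup:
            out.append(s)
    return out


def filter_origins(
    acs_list: list[AcsAnnotation],
    chrom_lengths: dict[str, int],
    tracks: dict[str, ProbeTrack] | None = None,
    max_dup: int = 9,
    flank: int = 800,
    dup_window: int = 800,
) -> list[AcsAnnotation]:
    """Drop origins without ``flank`` bp on both sides of the ACS, or with
    more than ``max_dup`` duplicated probes in the ``dup_window``-bp region
    centered on the ACS."""
    half = dup_window // 2
    kept = []
    for a in acs_list:
        clen = chrom_lengths[a.chrom]
        if a.acs_start - flank < 1 or a.acs_start + flank > clen:
            continue
        if tracks is not None and a.chrom in tracks:
            t = tracks[a.chrom]
            lo = np.searchsorted(t.coords, a.acs_start - half, side="left")
            hi = np.searchsorted(t.coords, a.acs_start + half, side="right")
            if int(t.dup_flags[lo:hi].sum()) > max_dup:
                continue
        kept.append(a)
    return kept


def filter_missing_calls(
    acs_list: list[AcsAnnotation],
    track_1bp: dict[str, ProbeTrack],
    max_missing: int = 40,
    half_width: int = 400,
) -> list[AcsAnnotation]:
    """Retain origins with at most ``max_missing`` missing calls among the
    801 positions of the 800-bp region centered on the ACS (for 1-bp
    resolution tracks such as the in-vitro map)."""
    kept = []
    for a in acs_list:
        t = track_1bp.get(a.chrom)
        if t is None:
            continue
        want = np.arange(a.acs_start - half_width, a.acs_start + half_width + 1)
        idx = np.searchsorted(t.coords, want)
        present = np.zeros(want.shape, dtype=bool)
        ok = idx < len(t.coords)
        present[ok] = t.coords[idx[ok]] == want[ok]
        n_missing = int((~present).sum())
        vals = np.full(want.shape, np.nan)
        vals[present] = t.values[idx[present]]
        n_missing += int(np.isnan(vals[present]).sum())
        if n_missing <= max_missing:
            kept.append(a)
    return kept


@dataclass
class AlignedMatrix:
    """Origins × relative-position grid of oriented log2 occupancy values.

    ``positions`` runs −half_width..+half_width in probe steps (401 slots
    for the default ±800 bp at 4 bp); after orientation, positive
    positions point toward the T-rich 3' (B1) side for every origin.
    """

    origin_ids: list[str]
    positions: np.ndarray  # (m,), bp relative to the ACS
    values: np.ndarray  # (n, m), NaN = no probe in slot
    orientation_applied: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.origin_ids), len(self.positions)):
            raise ValueError("values shape does not match origin_ids × positions")

    @property
    def n_origins(self) -> int:
        return len(self.origin_ids)

    def row(self, origin_id: str) -> np.ndarray:
        return self.values[self.origin_ids.index(origin_id)]

    def region_mask(self, region: tuple[int, int]) -> np.ndarray:
        lo, hi = region
        return (self.positions >= lo) & (self.positions <= hi)


def build_aligned_matrix(
    tracks: dict[str, ProbeTrack],
    acs_list: list[AcsAnnotation],
    half_width: int = 800,
    step: int = 4,
) -> AlignedMatrix:
    """Snap probes within ±``half_width`` bp of each ACS onto the relative
    probe grid and orient every origin T-rich 5'→3'.

    A grid slot takes the probe whose coordinate lies within ``step/2`` bp
    of the slot center (nearest wins, ties toward the lower genomic
    coordinate); slots with no such probe are NA. Origins on the Crick
    T-rich strand have their position axis reflected.
    """
    positions = np.arange(-half_width, half_width + 1, step, dtype=np.int64)
    m = len(positions)
    values = np.full((len(acs_list), m), np.nan)
    tol = step / 2.0

    for i, a in enumerate(acs_list):
        t = tracks.get(a.chrom)
        if t is None or len(t) == 0:
            warnings.warn(f"{a.origin_id}: no track coverage on {a.chrom}")
            continue
        centers = a.acs_start + a.orientation * positions  # genomic slot centers
        idx = np.clip(np.searchsorted(t.coords, centers), 0, len(t.coords) - 1)
        # candidate probes flanking each slot center
        left = np.clip(idx - 1, 0, len(t.coords) - 1)
        d_right = np.abs(t.coords[idx] - centers)
        d_left = np.abs(t.coords[left] - centers)
        # nearest probe; tie at equal distance -> lower genomic coordinate
        use_left = (d_left < d_right) | (
            (d_left == d_right) & (t.coords[left] < t.coords[idx])
        )
        chosen = np.where(use_left, left, idx)
        dist = np.where(use_left, d_left, d_right)
        ok = dist <= tol
        if not ok.any():
            warnings.warn(f"{a.origin_id}: outside track coverage on {a.chrom}")
            continue
        values[i, ok] = t.values[chosen[ok]]

    return AlignedMatrix(
        origin_ids=[a.origin_id for a in acs_list],
        positions=positions,
        values=values,
        orientation_applied=True,
    )


def reflect_matrix(matrix: AlignedMatrix) -> AlignedMatrix:
    """Reflect the position axis of every row (an involution)."""
    return AlignedMatrix(
        origin_ids=list(matrix.origin_ids),
        positions=matrix.positions.copy(),
        values=matrix.values[:, ::-1].copy(),
        orientation_applied=matrix.orientation_applied,
    )
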