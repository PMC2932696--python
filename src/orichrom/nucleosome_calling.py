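"""Per-origin nucleosome midpoint calling by template correlation.

Two 26-probe templates are cut from the average profile, centered on the
occupancy maxima flanking the NDR.  Each origin row is scanned with the
side-matching template; local maxima of the sliding Pearson correlation
that clear a cutoff (default 0.45) become nucleosome midpoints.  The NDR
width of an origin is the distance between its innermost calls on either
side of the ACS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .acs_alignment import AlignedMatrix
from .occupancy_profiles import (
    NdrGeometry,
    OriginProfile,
    loess_smooth,
    peak_to_peak_ndr,
)

__all__ = [
    "FlankTemplate",
    "NucleosomeCallSet",
    "WidthDistribution",
    "TEMPLATE_PROBES",
    "build_flank_templates",
    "build_flank_templates_from_matrix",
    "correlation_track",
    "call_midpoints",
    "call_matrix",
    "call_pipeline",
    "ndr_width",
    "ndr_width_distribution",
]

#: Calls closer than this are physically implausible (a nucleosome core
#: spans 147 bp); the strongest-correlation call wins.
MIN_SEPARATION_BP = 120

TEMPLATE_PROBES = 26

# The 26-probe window has no central probe; the two sides use mirrored
# cuts (right: 12 probes before the center, 13 after; left: 13 before,
# 12 after) so the left template of a symmetric profile is exactly the
# reversed right template.
_CENTER_INDEX = {"right": 12, "left": 13}


@dataclass
class FlankTemplate:
    """A 26-probe occupancy template around one flanking maximum."""

    side: str  # 'left' or 'right'
    values: np.ndarray
    center_pos: int  # bp relative to the ACS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if len(self.values) != TEMPLATE_PROBES:
            raise ValueError(f"template must have {TEMPLATE_PROBES} probes")
        if not np.isfinite(self.values).all():
            raise ValueError("template values must be finite")

    @property
    def center_index(self) -> int:
        """Index within the window aligned to the scored position."""
        return _CENTER_INDEX[self.side]


@dataclass
class NucleosomeCallSet:
    """Called nucleosome midpoints for one origin.

    Labels are ordinal by distance from the ACS: +1 is the innermost call
    at position >= 0, −1 the innermost at position < 0, ±2 the next
    outward, and so on.
    """

    origin_id: str
    midpoints: np.ndarray  # bp relative to the ACS, sorted
    scores: np.ndarray  # template correlation per midpoint
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        order = np.argsort(self.midpoints)
        self.midpoints = self.midpoints[order]
        self.scores = self.scores[order]
        if self.labels is None:
            neg = self.midpoints < 0
            labels = np.empty(len(self.midpoints), dtype=np.int64)
            labels[~neg] = np.arange(1, int((~neg).sum()) + 1)
            labels[neg] = -np.arange(int(neg.sum()), 0, -1)
            self.labels = labels
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)[order]

    def __len__(self) -> int:
        return len(self.midpoints)


def build_flank_templates(
    profile: OriginProfile, geometry: NdrGeometry | None = None
) -> tuple[FlankTemplate, FlankTemplate]:
    """Cut the two 26-probe templates around the average profile's flanking
    maxima.  A maximum within 13 probes of the grid edge leaves no room
    for a full window and raises ``ValueError``."""
    if geometry is None:
        geometry = peak_to_peak_ndr(profile)
    out = []
    for side, pos in (("left", geometry.left_pos), ("right", geometry.right_pos)):
        idx = int(np.flatnonzero(profile.positions == pos)[0])
        ci = _CENTER_INDEX[side]
        lo, hi = idx - ci, idx + (TEMPLATE_PROBES - ci)
        if lo < 0 or hi > len(profile.positions):
            raise ValueError(
                f"{side} maximum at {pos} bp is too close to the grid edge "
                f"for a {TEMPLATE_PROBES}-probe template"
            )
        vals = profile.mean_log2[lo:hi]
        if not np.isfinite(vals).all():
            raise ValueError(f"{side} template window contains NA")
        out.append(FlankTemplate(side, vals, pos))
    return out[0], out[1]


def build_flank_templates_from_matrix(
    matrix: AlignedMatrix,
    left_search: tuple[int, int] = (-400, -40),
    right_search: tuple[int, int] = (40, 400),
) -> tuple[FlankTemplate, FlankTemplate]:
    """Estimate flank templates by peak-aligned averaging over origins.

    For each origin row, the 26-probe window centered on the row's
    occupancy maximum inside each flank search window is extracted; the
    per-side average of these windows is the template.  When origins are
    homogeneous this converges to the template cut from the grand-average
    profile, but it stays peaked when NDR widths are heterogeneous and
    the grand average is smeared.  Rows should be smoothed first
    (``smooth_matrix``) so window centers are not picked on noise.
    """
    pos = matrix.positions
    out = []
    for side, (lo, hi) in (("left", left_search), ("right", right_search)):
        mask = (pos >= lo) & (pos <= hi)
        idxs = np.flatnonzero(mask)
        ci = _CENTER_INDEX[side]
        wins = []
        centers = []
        for row in matrix.values:
            v = np.where(np.isfinite(row[idxs]), row[idxs], -np.inf)
            if not np.isfinite(v).any():
                continue
            k = int(idxs[np.argmax(v)])
            if k - ci < 0 or k + (TEMPLATE_PROBES - ci) > len(pos):
                continue
            w = row[k - ci : k + (TEMPLATE_PROBES - ci)]
            if np.isfinite(w).all():
                wins.append(w)
                centers.append(int(pos[k]))
        if not wins:
            raise ValueError(f"no usable {side}-flank windows in any origin row")
        out.append(
            FlankTemplate(side, np.mean(wins, axis=0), int(np.median(centers)))
        )
    return out[0], out[1]


def correlation_track(
    origin_row: np.ndarray,
    template: FlankTemplate,
    min_overlap: int = 20,
) -> np.ndarray:
    """Pearson correlation of each sliding 26-probe window with the template.

    The value at index i correlates the window whose
    ``template.center_index``-th probe sits at i (``row[i-12 : i+14]``
    for a right-side template).  Windows with fewer than ``min_overlap``
    non-NA probes, or with zero variance over the overlap, are NA, as
    are edge positions without a full window.
    """
    row = np.asarray(origin_row, dtype=float)
    n = len(row)
    out = np.full(n, np.nan)
    if n < TEMPLATE_PROBES:
        return out
    ci = template.center_index
    win = sliding_window_view(row, TEMPLATE_PROBES)  # (n-25, 26)
    valid = np.isfinite(win)
    cnt = valid.sum(axis=1)
    t = template.values
    xw = np.where(valid, win, 0.0)
    tw = np.where(valid, t, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = xw.sum(1)
        st = tw.sum(1)
        cov = (xw * tw).sum(1) - sx * st / cnt
        vx = (xw * xw).sum(1) - sx * sx / cnt
        vt = (tw * tw).sum(1) - st * st / cnt
        r = cov / np.sqrt(vx * vt)
    scale = float(np.nanmax(np.abs(row))) if np.isfinite(row).any() else 1.0
    tiny = 1e-10 * max(scale * scale, 1.0)
    r[(cnt < min_overlap) | (vx <= tiny) | (vt <= tiny)] = np.nan
    out[ci : ci + len(r)] = r
    return np.clip(out, -1.0, 1.0)


def _local_maxima(track: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus collapse to their center.

    A maximum must be strictly greater than the finite values on both
    sides of its (possibly flat) summit; NA neighbours disqualify it.
    """
    n = len(track)
    out: list[int] = []
    i = 1
    while i < n - 1:
        v = track[i]
        if not np.isfinite(v):
            i += 1
            continue
        j = i
        while j + 1 < n and track[j + 1] == v:
            j += 1
        left = track[i - 1]
        right = track[j + 1] if j + 1 < n else np.nan
        if np.isfinite(left) and np.isfinite(right) and left < v and right < v:
            out.append((i + j) // 2)
        i = j + 1
    return out


def _suppress_close(peaks: list[int], scores: np.ndarray, min_slots: int) -> list[int]:
    """Greedy non-maximum suppression: keep highest-scoring peaks, drop
    any peak within ``min_slots`` of a kept one."""
    if min_slots <= 0 or len(peaks) < 2:
        return peaks
    order = sorted(range(len(peaks)), key=lambda i: -scores[i])
    kept: list[int] = []
    for i in order:
        if all(abs(peaks[i] - peaks[j]) >= min_slots for j in kept):
            kept.append(i)
    return sorted(peaks[i] for i in kept)


def call_midpoints(
    origin_row: np.ndarray,
    templates: tuple[FlankTemplate, FlankTemplate],
    positions: np.ndarray,
    cutoff: float = 0.45,
    origin_id: str = "",
    min_overlap: int = 20,
    min_separation_bp: int = MIN_SEPARATION_BP,
) -> NucleosomeCallSet:
    """Call nucleosome midpoints on one aligned origin row.

    The left template scores positions < 0 and the right template
    positions >= 0; local maxima of the combined correlation track with
    score >= cutoff become midpoints.  Maxima closer than
    ``min_separation_bp`` (sub-nucleosomal spacing) are resolved in
    favour of the higher correlation.  An empty call set is allowed.
    """
    left_t, right_t = templates
    positions = np.asarray(positions)
    track_l = correlation_track(origin_row, left_t, min_overlap)
    track_r = correlation_track(origin_row, right_t, min_overlap)
    track = np.where(positions < 0, track_l, track_r)
    peaks = [i for i in _local_maxima(track) if track[i] >= cutoff]
    if len(positions) > 1:
        step = int(positions[1] - positions[0])
        peaks = _suppress_close(peaks, track, min_separation_bp // step)
    return NucleosomeCallSet(
        origin_id=origin_id,
        midpoints=positions[peaks],
        scores=track[peaks],
    )


def call_matrix(
    matrix: AlignedMatrix,
    templates: tuple[FlankTemplate, FlankTemplate],
    cutoff: float = 0.45,
    min_overlap: int = 20,
    min_separation_bp: int = MIN_SEPARATION_BP,
) -> list[NucleosomeCallSet]:
    """Call midpoints for every origin row of an aligned matrix."""
    return [
        call_midpoints(
            matrix.values[i], templates, matrix.positions, cutoff,
            origin_id=oid, min_overlap=min_overlap,
            min_separation_bp=min_separation_bp,
        )
        for i, oid in enumerate(matrix.origin_ids)
    ]


def call_pipeline(
    matrix: AlignedMatrix,
    cutoff: float = 0.45,
    row_span_probes: int = 11,
    min_separation_bp: int = MIN_SEPARATION_BP,
) -> tuple[list[NucleosomeCallSet], dict[str, int | None]]:
    """Full per-origin calling pipeline: smooth rows, estimate flank
    templates by peak-aligned averaging, call midpoints, derive NDR widths.

    Returns the call sets and a per-origin NDR width map (None when a
    side has no call).
    """
    from .occupancy_profiles import smooth_matrix

    smoothed = smooth_matrix(matrix, row_span_probes)
    templates = build_flank_templates_from_matrix(smoothed)
    calls = call_matrix(
        smoothed, templates, cutoff=cutoff, min_separation_bp=min_separation_bp
    )
    widths = {cs.origin_id: ndr_width(cs) for cs in calls}
    return calls, widths


def ndr_width(calls: NucleosomeCallSet) -> int | None:
    """NDR width from the ACS-proximal calls on either side of the ACS:
    (smallest midpoint > 0) − (largest midpoint < 0).  ``None`` when a
    side has no call (excluded from distributions)."""
    pos = calls.midpoints[calls.midpoints > 0]
    neg = calls.midpoints[calls.midpoints < 0]
    if pos.size == 0 or neg.size == 0:
        return None
    return int(pos.min() - neg.max())


@dataclass
class WidthDistribution:
    """NDR width distribution: per-grid-point counts, an overlapping
    moving-sum view, and a LOESS-smoothed curve.

    ``counts`` sums to the number of widths; the moving sum counts each
    width once per window it falls in (``window_probes`` windows for
    interior widths).
    """

    width_grid: np.ndarray  # bp, probe-step spacing
    counts: np.ndarray
    moving_sum: np.ndarray
    smoothed: np.ndarray
    window_probes: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def ndr_width_distribution(
    widths,
    window_probes: int = 9,
    step: int = 4,
    span_probes: int = 9,
) -> WidthDistribution:
    """Moving-sum distribution of NDR widths over the probe-step grid.

    The grid is padded by one full window on each side so every width
    contributes to exactly ``window_probes`` moving windows.
    """
    widths = np.asarray([w for w in widths if w is not None], dtype=float)
    if widths.size == 0:
        raise ValueError("empty width list")
    pad = window_probes * step
    lo = step * int(np.floor(widths.min() / step)) - pad
    hi = step * int(np.ceil(widths.max() / step)) + pad
    grid = np.arange(lo, hi + 1, step)
    snapped = step * np.round(widths / step).astype(np.int64)
    counts = np.zeros(len(grid), dtype=np.int64)
    idx = ((snapped - lo) // step).astype(np.intp)
    np.add.at(counts, idx, 1)
    moving = np.convolve(counts, np.ones(window_probes, dtype=np.int64), "same")
    smoothed = loess_smooth(
        moving.astype(float), grid.astype(float), span_probes=max(span_probes, 3)
    )
    return WidthDistribution(grid, counts, moving, smoothed, window_probes)
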