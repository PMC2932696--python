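"""Averaging, smoothing, and geometry of ACS-aligned occupancy profiles.

The average origin profile is the per-position mean over origins of the
oriented log2 values, optionally LOESS-smoothed with a span encompassing a
fixed number of probes.  The nucleosome-depleted region (NDR) of an average
profile is measured peak-to-peak between the flanking occupancy maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .acs_alignment import AlignedMatrix

__all__ = [
    "OriginProfile",
    "BivariateHistogram",
    "NdrGeometry",
    "loess_smooth",
    "average_profile",
    "bivariate_histogram",
    "difference_profile",
    "peak_to_peak_ndr",
    "free_dna_span",
]

#: Core DNA within the two nucleosomes flanking an NDR (2 × 73 bp).
FLANKING_NUCLEOSOME_DNA = 146


@dataclass
class OriginProfile:
    """Average occupancy profile: per-position mean log2 over origins."""

    positions: np.ndarray
    mean_log2: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.mean_log2 = np.asarray(self.mean_log2, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=np.int64)


@dataclass
class BivariateHistogram:
    """2-D (position, log2) histogram of all non-NA matrix cells — a
    two-dimensional error bar for the mean profile.  Rectangular bins."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NdrGeometry:
    """Peak-to-peak NDR measurement on an average profile."""

    width: float  # bp between the flanking occupancy maxima
    center: float  # midpoint of the two maxima, bp relative to the ACS
    left_pos: int
    right_pos: int


def loess_smooth(
    values: np.ndarray,
    positions: np.ndarray | None = None,
    span_probes: int = 36,
) -> np.ndarray:
    """Locally weighted linear (LOESS, tricube) smoothing on the probe grid.

    The span is expressed as a probe count: the fit at each position uses
    the ``span_probes`` nearest non-NA neighbours.  Constants and exact
    lines are reproduced unchanged.  NA values are ignored for fitting and
    the smooth is evaluated at every position.
    """
    values = np.asarray(values, dtype=float)
    if positions is None:
        positions = np.arange(len(values))
    positions = np.asarray(positions, dtype=float)
    if span_probes < 3:
        raise ValueError("span_probes must be >= 3")
    ok = np.isfinite(values)
    n_ok = int(ok.sum())
    if n_ok < 3:
        raise ValueError(f"need >=3 non-NA points to smooth, got {n_ok}")
    frac = min(1.0, span_probes / n_ok)
    return _lowess(
        values[ok], positions[ok], frac=frac, it=0, xvals=positions
    )


def smooth_matrix(matrix: AlignedMatrix, span_probes: int = 9) -> AlignedMatrix:
    """LOESS-smooth every origin row of an aligned matrix.

    Rows with fewer than 3 non-NA values are passed through unchanged.
    A short span suppresses per-probe noise while leaving occupancy peak
    positions in place.
    """
    out = np.empty_like(matrix.values)
    for i, row in enumerate(matrix.values):
        if np.isfinite(row).sum() < 3:
            out[i] = row
        else:
            out[i] = loess_smooth(row, matrix.positions, span_probes)
    return AlignedMatrix(
        origin_ids=list(matrix.origin_ids),
        positions=matrix.positions.copy(),
        values=out,
        orientation_applied=matrix.orientation_applied,
    )


def average_profile(
    matrix: AlignedMatrix, smooth: bool = False, span_probes: int = 36
) -> OriginProfile:
    """Per-position mean of non-NA values over all origins."""
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(matrix.values, axis=0)
    n = np.isfinite(matrix.values).sum(axis=0)
    if smooth:
        mean = loess_smooth(mean, matrix.positions, span_probes)
    return OriginProfile(matrix.positions, mean, n)


def bivariate_histogram(
    matrix: AlignedMatrix, nx: int = 50, ny: int = 40
) -> BivariateHistogram:
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    pos = np.broadcast_to(matrix.positions, matrix.values.shape)
    ok = np.isfinite(matrix.values)
    counts, x_edges, y_edges = np.histogram2d(
        pos[ok], matrix.values[ok], bins=(nx, ny)
    )
    return BivariateHistogram(x_edges, y_edges, counts)


def difference_profile(
    matrix_a: AlignedMatrix, matrix_b: AlignedMatrix
) -> OriginProfile:
    """Per-position mean of (a − b) over origins where both are non-NA.

    Used to contrast conditions (e.g. ORC-depleted vs wild type) on the
    same origin set.
    """
    if matrix_a.origin_ids != matrix_b.origin_ids:
        raise ValueError("matrices do not share origin ids")
    if not np.array_equal(matrix_a.positions, matrix_b.positions):
        raise ValueError("matrices do not share the position grid")
    diff = matrix_a.values - matrix_b.values  # NaN where either is NA
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(diff, axis=0)
    n = np.isfinite(diff).sum(axis=0)
    return OriginProfile(matrix_a.positions, mean, n)


def _window_argmax(profile: OriginProfile, lo: int, hi: int) -> int:
    mask = (profile.positions >= lo) & (profile.positions <= hi)
    idx = np.flatnonzero(mask)
    if idx.size < 3:
        raise ValueError(f"search window ({lo},{hi}) covers <3 grid positions")
    vals = profile.mean_log2[idx]
    if not np.isfinite(vals).all():
        idx = idx[np.isfinite(vals)]
        vals = profile.mean_log2[idx]
        if idx.size < 3:
            raise ValueError(f"search window ({lo},{hi}) is mostly NA")
    k = int(np.argmax(vals))
    if k == 0 or k == len(vals) - 1:
        raise ValueError(
            f"no interior occupancy maximum in window ({lo},{hi}); "
            "profile may be monotone there"
        )
    return int(idx[k])


def peak_to_peak_ndr(
    profile: OriginProfile,
    left_search: tuple[int, int] = (-400, -40),
    right_search: tuple[int, int] = (40, 400),
) -> NdrGeometry:
    """Measure the NDR of a (smoothed) average profile peak-to-peak.

    The flanking −1/+1 nucleosome midpoints are taken as the interior
    occupancy maxima inside the two search windows; width is their
    separation and center their midpoint.  A window whose maximum sits on
    its boundary has no interior peak and raises ``ValueError``.
    """
    li = _window_argmax(profile, *left_search)
    ri = _window_argmax(profile, *right_search)
    lp = int(profile.positions[li])
    rp = int(profile.positions[ri])
    return NdrGeometry(
        width=float(rp - lp), center=(lp + rp) / 2.0, left_pos=lp, right_pos=rp
    )


def free_dna_span(width: float) -> float:
    """Nucleosome-free DNA inside a peak-to-peak NDR width.

    Subtracts the 146 bp occupied by the inner halves of the two flanking
    nucleosomes (2 × 73 bp from midpoint to inner edge).
    """
    if width < FLANKING_NUCLEOSOME_DNA:
        raise ValueError(
            f"width {width} bp is smaller than the {FLANKING_NUCLEOSOME_DNA} bp "
            "covered by the flanking nucleosomes"
        )
    return width - FLANKING_NUCLEOSOME_DNA
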