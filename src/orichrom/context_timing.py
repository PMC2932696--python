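"""Genomic context and replication timing around origins.

Distances from the ACS to nearby features (TSSs, gene ends, centromeres,
telomeres, neighbouring ARSs) are signed along the oriented origin axis
(positive toward the T-rich 3' side).  Feature distributions are
summarized by 25-probe moving sums; replication-timing statistics (early
origin proportion in hydroxyurea, mean Trep) are computed per window and
masked when fewer than 5 origins contribute.  Significance is assessed by
resampling same-sized origin groups from the full set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import AcsAnnotation, FeatureRecord, TimingRecord
from .occupancy_profiles import loess_smooth

__all__ = [
    "ContextAnnotation",
    "WindowedStat",
    "MovingSumResult",
    "QuantileBin",
    "annotate_context",
    "feature_offsets",
    "moving_sum_distribution",
    "windowed_timing",
    "assign_trep",
    "resample_proportion_test",
    "ndr_quantile_timing",
]

MIN_ORIGINS_PER_WINDOW = 5  # windows with fewer origins are masked


@dataclass
class ContextAnnotation:
    """Signed oriented distance from one origin's ACS to the nearest
    feature of each kind (None when the chromosome lacks the feature)."""

    origin_id: str
    distances: dict[str, int | None]


@dataclass
class WindowedStat:
    center: int  # bp relative to the ACS (window midpoint)
    value: float  # count / proportion / mean Trep
    n_origins: int
    masked: bool


@dataclass
class MovingSumResult:
    positions: np.ndarray
    counts: np.ndarray  # per-slot feature counts (sums to the input total)
    moving_sum: np.ndarray  # overlapping window sums, center = midpoint
    smoothed: np.ndarray
    window_probes: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _oriented(acs: AcsAnnotation, coord: int) -> int:
    return (coord - acs.acs_start) * acs.orientation


def annotate_context(
    acs_list: list[AcsAnnotation], features: list[FeatureRecord]
) -> list[ContextAnnotation]:
    """Nearest-feature signed distances per origin and feature kind."""
    by_kind_chrom: dict[tuple[str, str], np.ndarray] = {}
    for f in features:
        by_kind_chrom.setdefault((f.kind, f.chrom), []).append(f.coord)  # type: ignore[attr-defined]
    by_kind_chrom = {
        key: np.sort(np.asarray(v, dtype=np.int64))
        for key, v in by_kind_chrom.items()
    }
    kinds = sorted({f.kind for f in features})
    out = []
    for a in acs_list:
        dists: dict[str, int | None] = {}
        for kind in kinds:
            coords = by_kind_chrom.get((kind, a.chrom))
            if coords is None or coords.size == 0:
                dists[kind] = None
                continue
            i = int(np.argmin(np.abs(coords - a.acs_start)))
            dists[kind] = _oriented(a, int(coords[i]))
        out.append(ContextAnnotation(a.origin_id, dists))
    return out


def feature_offsets(
    acs_list: list[AcsAnnotation],
    features: list[FeatureRecord],
    kind: str,
    max_abs: int = 800,
) -> dict[str, list[int]]:
    """All oriented offsets of ``kind`` features within ±``max_abs`` bp of
    each origin's ACS."""
    by_chrom: dict[str, list[int]] = {}
    for f in features:
        if f.kind == kind:
            by_chrom.setdefault(f.chrom, []).append(f.coord)
    by_chrom = {c: np.sort(np.asarray(v)) for c, v in by_chrom.items()}
    out: dict[str, list[int]] = {}
    for a in acs_list:
        coords = by_chrom.get(a.chrom)
        offs: list[int] = []
        if coords is not None:
            lo = np.searchsorted(coords, a.acs_start - max_abs, side="left")
            hi = np.searchsorted(coords, a.acs_start + max_abs, side="right")
            offs = [_oriented(a, int(c)) for c in coords[lo:hi]]
            offs = [o for o in offs if abs(o) <= max_abs]
        out[a.origin_id] = sorted(offs)
    return out


def _slot_grid(half_width: int, step: int) -> np.ndarray:
    return np.arange(-half_width, half_width + 1, step, dtype=np.int64)


def moving_sum_distribution(
    offsets,
    window_probes: int = 25,
    half_width: int = 800,
    step: int = 4,
    span_probes: int = 26,
) -> MovingSumResult:
    """Moving-sum count distribution of feature offsets on the probe grid.

    Offsets are snapped to the nearest grid slot; the moving sum over
    ``window_probes`` slots is centered on the window midpoint and then
    LOESS-smoothed with a span encompassing ``span_probes`` probes.  The
    per-slot counts conserve the input total.
    """
    grid = _slot_grid(half_width, step)
    counts = np.zeros(len(grid), dtype=np.int64)
    for o in offsets:
        if abs(o) > half_width:
            continue
        counts[int(round((o + half_width) / step))] += 1
    moving = np.convolve(counts, np.ones(window_probes, dtype=np.int64), "same")
    smoothed = loess_smooth(moving.astype(float), grid.astype(float), span_probes)
    return MovingSumResult(grid, counts, moving, smoothed, window_probes)


def windowed_timing(
    offsets_by_origin: dict[str, list[int]],
    timing: dict[str, TimingRecord],
    statistic: str = "early_proportion",
    window_probes: int = 25,
    half_width: int = 800,
    step: int = 4,
) -> list[WindowedStat]:
    """Per-window replication-timing statistic over origins whose feature
    (TSS or gene end) falls in the window.

    ``statistic`` is ``early_proportion`` (fraction of HU-early origins)
    or ``mean_trep`` (mean Trep in minutes over origins with a value).
    Windows with fewer than 5 contributing origins are masked.  Origins
    without a timing record are excluded with a warning.
    """
    if statistic not in ("early_proportion", "mean_trep"):
        raise ValueError(f"unknown statistic {statistic!r}")
    grid = _slot_grid(half_width, step)
    half_win = window_probes // 2
    slots_by_origin: dict[str, np.ndarray] = {}
    n_missing = 0
    for oid, offs in offsets_by_origin.items():
        if not offs:
            continue
        if oid not in timing:
            n_missing += 1
            continue
        slots_by_origin[oid] = np.unique(
            [int(round((o + half_width) / step)) for o in offs if abs(o) <= half_width]
        )
    if n_missing:
        warnings.warn(f"windowed_timing: {n_missing} origin(s) missing timing")

    out = []
    for j, center in enumerate(grid):
        lo, hi = j - half_win, j + half_win
        members = [
            oid for oid, slots in slots_by_origin.items()
            if slots.size and slots[0] <= hi and slots[-1] >= lo
            and np.any((slots >= lo) & (slots <= hi))
        ]
        n = len(members)
        if statistic == "early_proportion":
            vals = [float(timing[oid].early) for oid in members]
        else:
            vals = [timing[oid].trep for oid in members
                    if timing[oid].trep is not None]
        value = float(np.mean(vals)) if vals else float("nan")
        out.append(
            WindowedStat(int(center), value, n, masked=n < MIN_ORIGINS_PER_WINDOW)
        )
    return out


def assign_trep(
    acs_start: int, coords: np.ndarray, treps: np.ndarray
) -> float:
    """Trep of the timing data point nearest the ACS; ties take the lower
    coordinate."""
    coords = np.asarray(coords, dtype=np.int64)
    treps = np.asarray(treps, dtype=float)
    if coords.size == 0:
        raise ValueError("empty timing track")
    order = np.argsort(coords, kind="stable")
    coords, treps = coords[order], treps[order]
    i = int(np.argmin(np.abs(coords - acs_start)))  # argmin takes first = lower
    return float(treps[i])


def resample_proportion_test(
    labels: np.ndarray,
    subset_idx: np.ndarray,
    reps: int = 10000,
    seed: int = 0,
) -> float:
    """Percentile of a subset's early-origin proportion under resampling.

    Draws ``reps`` same-sized samples without replacement from the full
    origin set and returns the percentage of samples whose early
    proportion is strictly below the subset's observed proportion.
    """
    labels = np.asarray(labels, dtype=bool)
    subset_idx = np.asarray(subset_idx)
    n, k = labels.size, subset_idx.size
    if k > n:
        raise ValueError(f"subset of {k} exceeds the set of {n}")
    if k == 0:
        raise ValueError("empty subset")
    observed = labels[subset_idx].mean()
    rng = np.random.default_rng(seed)
    keys = rng.random((reps, n))
    pick = np.argpartition(keys, k - 1, axis=1)[:, :k]
    props = labels[pick].mean(axis=1)
    return float(100.0 * np.mean(props < observed))


@dataclass
class QuantileBin:
    width_range: tuple[float, float]
    origin_ids: list[str]
    early_proportion: float
    percentile: float  # % of resamples strictly below the bin's proportion


def ndr_quantile_timing(
    widths: dict[str, float],
    timing: dict[str, TimingRecord],
    n_quantiles: int = 7,
    reps: int = 10000,
    seed: int = 0,
    background_ids: list[str] | None = None,
) -> list[QuantileBin]:
    """Early-origin proportion per NDR-width quantile, each scored against
    resamples from the full origin set.

    Origins with a defined width and a timing record are sorted by width
    (stable; ties keep input order, i.e. go to the lower bin) and split
    into ``n_quantiles`` groups whose sizes differ by at most one.  The
    resampling background is ``background_ids`` (default: every origin
    with a timing record).
    """
    ids = [oid for oid, w in widths.items() if w is not None and oid in timing]
    if n_quantiles > len(ids):
        raise ValueError(f"{n_quantiles} quantiles for only {len(ids)} origins")
    w = np.array([widths[oid] for oid in ids], dtype=float)
    if np.all(w == w[0]):
        raise ValueError("degenerate quantiles: all widths identical")
    if background_ids is None:
        background_ids = [oid for oid in timing]
    labels = np.array([timing[oid].early for oid in background_ids], dtype=bool)
    pos = {oid: i for i, oid in enumerate(background_ids)}

    order = np.argsort(w, kind="stable")
    bins = np.array_split(order, n_quantiles)
    out = []
    for b, idx in enumerate(bins):
        bin_ids = [ids[i] for i in idx]
        subset = np.array([pos[oid] for oid in bin_ids])
        pct = resample_proportion_test(labels, subset, reps=reps,
                                       seed=seed + b)
        out.append(
            QuantileBin(
                width_range=(float(w[idx].min()), float(w[idx].max())),
                origin_ids=bin_ids,
                early_proportion=float(labels[subset].mean()),
                percentile=pct,
            )
        )
    return out
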