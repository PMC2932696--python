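"""GC and dinucleotide structural-property profiles around the ACS.

Properties are scored in sliding windows (default 75 bp): the dinucleotide
counts in a window are multiplied by the property values, summed, and
divided by the number of (unambiguous) dinucleotides in the window; the
result is assigned to the window's central probe.  Average profiles are
rescaled to [−1, 1], LOESS-smoothed, restricted to the two-nucleosome
region around the ACS and grouped by k-means.

All profiles are computed on the oriented (T-rich 5'→3') strand, matching
the occupancy matrix orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import DINUCLEOTIDES, DinucleotidePropertyTable
from .occupancy_profiles import OriginProfile, loess_smooth

__all__ = [
    "PropertyProfile",
    "PropertyClusterResult",
    "extract_oriented_seqs",
    "gc_profile",
    "dinuc_window_profile",
    "average_property_profile",
    "rescale_unit",
    "prepare_property_profiles",
    "cluster_property_profiles",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PropertyProfile:
    """One sequence property averaged over oriented origins, per probe."""

    property_id: str
    positions: np.ndarray
    values: np.ndarray
    rescaled: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)


def extract_oriented_seqs(
    genome, acs_list, half_width: int = 800, window: int = 75
) -> list[str]:
    """Extract the T-rich-oriented sequence around each origin's ACS.

    Each sequence covers ±(half_width + window//2) bp around the ACS
    start so every grid probe gets a full scoring window; Crick-strand
    origins are reverse-complemented so all sequences read T-rich 5'→3'.
    """
    from .acs_alignment import revcomp

    reach = half_width + window // 2
    out = []
    for a in acs_list:
        seq = genome[a.chrom]
        lo, hi = a.acs_start - reach, a.acs_start + reach  # 1-based inclusive
        if lo < 1 or hi > len(seq):
            raise ValueError(
                f"{a.origin_id}: ±{reach} bp window leaves the chromosome"
            )
        s = seq[lo - 1 : hi].upper()
        out.append(s if a.orientation == 1 else revcomp(s))
    return out


def _grid(half_width: int, step: int) -> np.ndarray:
    return np.arange(-half_width, half_width + 1, step, dtype=np.int64)


def _check_seq_len(seq: str, half_width: int, margin: int) -> None:
    need = 2 * (half_width + margin) + 1
    if len(seq) < need:
        raise ValueError(
            f"sequence of {len(seq)} bp too short: need {need} bp "
            f"(±{half_width} bp grid plus {margin} bp window margin)"
        )


def _windowed_mean(per_pos: np.ndarray, n_items: int, centers: np.ndarray,
                   left: int, right: int) -> np.ndarray:
    """Mean of ``per_pos`` (NaN = excluded) over [c−left, c+right] windows."""
    vals = np.nan_to_num(per_pos, nan=0.0)
    ok = np.isfinite(per_pos).astype(float)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    cok = np.concatenate(([0.0], np.cumsum(ok)))
    lo = centers - left
    hi = centers + right + 1  # exclusive
    tot = csum[hi] - csum[lo]
    n = cok[hi] - cok[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = tot / n
    out[n == 0] = np.nan
    return out


def gc_profile(
    oriented_seqs: list[str],
    half_width: int = 800,
    step: int = 4,
    window: int = 75,
) -> PropertyProfile:
    """Windowed GC fraction per probe, averaged over oriented origins.

    Each sequence must cover the ±``half_width`` grid plus a
    ``window//2`` margin on both sides; ambiguous bases are excluded from
    numerator and denominator.
    """
    margin = window // 2
    grid = _grid(half_width, step)
    rows = []
    for seq in oriented_seqs:
        _check_seq_len(seq, half_width, margin)
        seq = seq.upper()
        mid = len(seq) // 2  # ACS anchor at the sequence center
        per_pos = np.full(len(seq), np.nan)
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        per_pos[(arr == ord("G")) | (arr == ord("C"))] = 1.0
        per_pos[(arr == ord("A")) | (arr == ord("T"))] = 0.0
        centers = (mid + grid).astype(np.intp)
        rows.append(_windowed_mean(per_pos, len(seq), centers, margin, margin))
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(np.vstack(rows), axis=0)
    return PropertyProfile("GC", grid, avg)


def dinuc_window_profile(
    oriented_seq: str,
    prop: DinucleotidePropertyTable,
    half_width: int = 800,
    step: int = 4,
    window: int = 75,
) -> np.ndarray:
    """Property score per probe for one oriented sequence.

    A ``window``-bp window centered on a probe holds ``window − 1``
    overlapping dinucleotides; the score is the property-weighted
    dinucleotide count divided by the number of unambiguous dinucleotides
    in the window.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd (centered on a probe)")
    margin = window // 2
    _check_seq_len(oriented_seq, half_width, margin)
    seq = oriented_seq.upper()
    mid = len(seq) // 2
    codes = np.array([_BASE_INDEX.get(b, -1) for b in seq], dtype=np.int64)
    first, second = codes[:-1], codes[1:]
    valid = (first >= 0) & (second >= 0)
    table = prop.as_array()
    dn_vals = np.full(len(seq) - 1, np.nan)
    dn_vals[valid] = table[(first * 4 + second)[valid]]
    grid = _grid(half_width, step)
    centers = (mid + grid).astype(np.intp)
    # dinucleotide i spans bases i..i+1: a window [c-m, c+m] holds
    # dinucleotides c-m .. c+m-1
    return _windowed_mean(dn_vals, len(seq) - 1, centers, margin, margin - 1)


def average_property_profile(
    oriented_seqs: list[str],
    prop: DinucleotidePropertyTable,
    half_width: int = 800,
    step: int = 4,
    window: int = 75,
) -> PropertyProfile:
    rows = [
        dinuc_window_profile(s, prop, half_width, step, window)
        for s in oriented_seqs
    ]
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(np.vstack(rows), axis=0)
    return PropertyProfile(prop.property_id, _grid(half_width, step), avg)


def rescale_unit(values: np.ndarray) -> np.ndarray:
    """Linear map of finite values onto [−1, 1] (min→−1, max→+1)."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 2 or finite.max() == finite.min():
        raise ValueError("rescale_unit needs >=2 distinct finite values")
    lo, hi = finite.min(), finite.max()
    return -1.0 + 2.0 * (values - lo) / (hi - lo)


def prepare_property_profiles(
    profiles: list[PropertyProfile],
    span_bp: int = 76,
    step: int = 4,
) -> list[PropertyProfile]:
    """Rescale each average profile to [−1, 1] and LOESS-smooth it with a
    span of ``span_bp`` (in probes: span_bp // step)."""
    span_probes = max(span_bp // step, 3)
    out = []
    for p in profiles:
        vals = loess_smooth(rescale_unit(p.values), p.positions, span_probes)
        out.append(PropertyProfile(p.property_id, p.positions, vals, rescaled=True))
    return out


@dataclass
class PropertyClusterResult:
    property_ids: list[str]
    assignments: np.ndarray  # cluster index per property, 0..k-1
    group_means: np.ndarray  # (k, m)
    positions: np.ndarray
    inertia: float
    heatmap_order: np.ndarray  # row order: groups ascending, within-group
    # by correlation with the group mean (descending)
    occupancy_correlations: np.ndarray | None = None  # (k,), vs mean profile


def cluster_property_profiles(
    profiles: list[PropertyProfile],
    region: tuple[int, int] = (-372, 424),
    k: int = 6,
    seed: int = 0,
    max_iter: int = 10000,
    occupancy_profile: OriginProfile | None = None,
) -> PropertyClusterResult:
    """Group rescaled, smoothed property profiles by k-means on the
    two-nucleosome region around the ACS.

    Reports each group's mean profile and, when an occupancy profile is
    supplied, the Pearson correlation of each group mean with the average
    occupancy profile over the same region.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds the {len(profiles)} profiles")
    positions = profiles[0].positions
    mask = (positions >= region[0]) & (positions <= region[1])
    X = np.vstack([p.values[mask] for p in profiles])
    if not np.isfinite(X).all():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isfinite(X), X, col_means)
    km = KMeans(n_clusters=k, n_init=1, max_iter=max_iter, tol=0.0,
                random_state=seed).fit(X)
    assign = km.labels_
    means = np.vstack([X[assign == g].mean(axis=0) for g in range(k)])

    occ_corr = None
    if occupancy_profile is not None:
        # evaluate the occupancy profile on this grid (the grids may differ)
        ok = np.isfinite(occupancy_profile.mean_log2)
        occ = np.interp(
            positions[mask].astype(float),
            occupancy_profile.positions[ok].astype(float),
            occupancy_profile.mean_log2[ok],
        )
        occ_corr = np.array([_pearson(means[g], occ) for g in range(k)])

    order = []
    for g in range(k):
        rows = np.flatnonzero(assign == g)
        corr = np.array([_pearson(X[r], means[g]) for r in rows])
        order.extend(rows[np.argsort(-corr)])
    return PropertyClusterResult(
        property_ids=[p.property_id for p in profiles],
        assignments=assign,
        group_means=means,
        positions=positions[mask],
        inertia=float(km.inertia_),
        heatmap_order=np.asarray(order, dtype=np.intp),
        occupancy_correlations=occ_corr,
    )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
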