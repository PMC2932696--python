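"""Synthetic origin-chromatin data with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
4-bp tiling-probe grid with missing and duplicated probes; origins with a
central nucleosome depletion of configurable width flanked by phased
nucleosome arrays whose positioning decays with distance; 15-bp ACS
motifs embedded in AT-rich cores of a random genome; TSS and gene-end
placements at configurable oriented offsets; and early/late replication
timing labels.  Occupancy is built directly in log2 space (bumps ≈ +1,
central depletion ≈ −1.5), mimicking the dynamic range of nucleosomal
tiling arrays.

Every generator is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io_formats import (
    AcsAnnotation,
    FeatureRecord,
    ProbeTrack,
    TimingRecord,
)

__all__ = [
    "ArchParams",
    "SyntheticTruth",
    "DEFAULT_MOTIF",
    "generate_occupancy",
    "generate_genome_with_acs",
    "generate_features_and_timing",
]

#: A T-rich 15-mer matching the ACS consensus layout.
DEFAULT_MOTIF = "TTTTATGTTTAGTTT"

#: Oriented TSS offsets emulating the observed non-uniform TSS
#: distribution around origins (peaks left of and right of the ACS).
DEFAULT_TSS_OFFSETS = (-276, 112, 328)
DEFAULT_GENE_END_OFFSETS = (-420, 240)

_CHROM = "chrS1"
_SPACING = 4000  # bp between planted origins; windows never overlap
_MARGIN = 2000


@dataclass
class ArchParams:
    """Origin architecture parameters (bp unless noted).

    ``width_low``/``width_high`` bound the uniform NDR-width distribution;
    ``period`` is the inter-nucleosome midpoint distance (147-bp core +
    linker); ``jitter_growth`` is the per-step growth of the positional
    jitter SD, so distal nucleosomes are progressively less well
    positioned (statistical positioning decay); ``noise_sd`` is the
    per-probe Gaussian noise SD in log2 units.
    """

    width_low: float = 160.0
    width_high: float = 500.0
    center_offset: float = 0.0  # NDR center relative to the ACS
    period: float = 165.0
    # bp of positional jitter SD per nucleosome step outward: the +1/-1
    # nucleosomes are exactly placed and distal ones progressively smear
    # (SD ~60 bp by the fourth), so average peak-to-trough height decays
    # with distance from the origin as on real chromosomes.
    jitter_growth: float = 20.0
    bump_amp: float = 1.0  # log2 height of a positioned nucleosome
    bump_sd: float = 50.0  # Gaussian footprint SD
    depletion_amp: float = 1.5  # log2 depth of the central depletion
    # The depletion is a raised-cosine trough with compact support ending
    # this many bp inside the innermost midpoints.  73 bp is the distance
    # from a nucleosome midpoint to its inner edge, so the trough lies
    # strictly between the flanking nucleosome cores and the observable
    # flanking maxima coincide exactly with the planted midpoints.
    depletion_inset: float = 73.0
    # Nucleosomes per side, innermost included; None plants arrays out to
    # one period beyond the probe window, so every in-window nucleosome
    # has flanking neighbours just as on a real chromosome.
    n_flank_nucs: int | None = None
    noise_sd: float = 0.2
    na_fraction: float = 0.05
    dup_fraction: float = 0.02

    def validate(self) -> None:
        if self.width_low <= 0 or self.width_high < self.width_low:
            raise ValueError("invalid width range")
        if self.period < 147:
            raise ValueError("period must be >= 147 bp (nucleosome core)")
        for name in ("bump_sd", "bump_amp", "depletion_amp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.na_fraction < 1 and 0 <= self.dup_fraction < 1):
            raise ValueError("na_fraction and dup_fraction must be in [0,1)")
        if self.n_flank_nucs is not None and self.n_flank_nucs < 1:
            raise ValueError("n_flank_nucs must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth for one planted origin (oriented coordinates)."""

    origin_id: str
    chrom: str
    acs_start: int
    t_rich_strand: str
    ndr_width: float
    midpoints: list[float]  # bp relative to the ACS, oriented
    period: float
    jitter_growth: float
    noise_sd: float
    tss_offsets: list[int] = field(default_factory=list)
    gene_end_offsets: list[int] = field(default_factory=list)
    early: bool | None = None
    trep: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _plant_midpoints(
    rng: np.random.Generator, arch: ArchParams, coverage: float
) -> tuple[float, list[float]]:
    """Draw an NDR width and build the flanking midpoint array.

    The innermost pair sits exactly at center ± width/2; further
    nucleosomes step outward by the period plus jitter whose SD grows
    with the step index (statistical-positioning decay).  Arrays extend
    to ``coverage`` bp from the center (or ``n_flank_nucs`` per side
    when set).
    """
    width = float(rng.uniform(arch.width_low, arch.width_high))
    c = arch.center_offset
    if arch.n_flank_nucs is not None:
        n_per_side = arch.n_flank_nucs
    else:
        n_per_side = 1 + int(np.ceil((coverage - width / 2.0) / arch.period))
    mids: list[float] = []
    for sign in (-1, +1):
        mids.append(c + sign * width / 2.0)
        for k in range(1, n_per_side):
            jitter = (
                rng.normal(0.0, arch.jitter_growth * k)
                if arch.jitter_growth > 0
                else 0.0
            )
            mids.append(c + sign * (width / 2.0 + k * arch.period) + jitter)
    mids.sort()
    return width, mids


def _occupancy(positions: np.ndarray, mids: list[float], center: float,
               width: float, arch: ArchParams) -> np.ndarray:
    out = np.zeros(len(positions))
    for m in mids:
        out += arch.bump_amp * np.exp(-0.5 * ((positions - m) / arch.bump_sd) ** 2)
    radius = max(width / 2.0 - arch.depletion_inset, 10.0)
    x = np.clip((positions - center) / radius, -1.0, 1.0)
    out -= arch.depletion_amp * np.cos(np.pi * x / 2.0) ** 2
    return out


def generate_occupancy(
    n_origins: int,
    arch: ArchParams | None = None,
    probe_step: int = 4,
    seed: int = 0,
    window_half: int = 1000,
) -> tuple[dict[str, ProbeTrack], list[AcsAnnotation], list[SyntheticTruth]]:
    """Generate probe tracks, ACS annotations, and ground truth.

    Origins are laid out on one synthetic chromosome, each covered by
    probes every ``probe_step`` bp within ±``window_half`` bp of its ACS.
    Occupancy is the sum of Gaussian bumps at the planted midpoints minus
    a central depletion, evaluated on the oriented axis, plus seeded
    Gaussian noise; strand, missing probes (NA) and duplicated-probe
    flags are drawn at the configured rates.
    """
    arch = arch or ArchParams()
    arch.validate()
    rng = np.random.default_rng(seed)
    acs_list: list[AcsAnnotation] = []
    truths: list[SyntheticTruth] = []
    coords_all: list[np.ndarray] = []
    values_all: list[np.ndarray] = []
    dups_all: list[np.ndarray] = []

    rel = np.arange(-window_half, window_half + 1, probe_step, dtype=np.int64)
    for i in range(n_origins):
        acs = _MARGIN + i * _SPACING
        strand = "W" if rng.random() < 0.5 else "C"
        orient = 1 if strand == "W" else -1
        width, mids = _plant_midpoints(rng, arch, window_half + arch.period)
        oriented_pos = orient * rel  # oriented position of each probe
        vals = _occupancy(
            oriented_pos.astype(float), mids, arch.center_offset, width, arch
        )
        if arch.noise_sd > 0:
            vals = vals + rng.normal(0.0, arch.noise_sd, size=len(vals))
        if arch.na_fraction > 0:
            vals[rng.random(len(vals)) < arch.na_fraction] = np.nan
        dups = rng.random(len(vals)) < arch.dup_fraction
        oid = f"syn{i:04d}"
        acs_list.append(AcsAnnotation(oid, _CHROM, acs, strand, "synthetic"))
        truths.append(
            SyntheticTruth(
                origin_id=oid, chrom=_CHROM, acs_start=acs,
                t_rich_strand=strand, ndr_width=width, midpoints=mids,
                period=arch.period, jitter_growth=arch.jitter_growth,
                noise_sd=arch.noise_sd,
            )
        )
        coords_all.append(acs + rel)
        values_all.append(vals)
        dups_all.append(dups)

    track = ProbeTrack(
        chrom=_CHROM,
        coords=np.concatenate(coords_all),
        values=np.concatenate(values_all),
        dup_flags=np.concatenate(dups_all),
    )
    return {_CHROM: track}, acs_list, truths


def generate_genome_with_acs(
    n_origins: int,
    motif: str = DEFAULT_MOTIF,
    at_core_len: int = 150,
    seed: int = 0,
    background_gc: float = 0.38,
    core_gc: float = 0.10,
    max_redraws: int = 50,
) -> tuple[dict[str, str], list[AcsAnnotation]]:
    """Random genome with one 15-bp ACS motif planted per origin inside an
    AT-rich core.

    The planted strand is randomized: Crick-strand origins carry the
    reverse complement so the T-rich motif reads 5'→3' on the Crick
    strand.  If the motif occurs more than once within ±1 kb of a planted
    site, the surrounding background is redrawn until it is locally
    unique.
    """
    if len(motif) != 15:
        raise ValueError("motif must be 15 bp")
    motif = motif.upper()
    at = motif.count("A") + motif.count("T")
    if at < 10:
        raise ValueError("motif must be T/A-rich on the planted strand")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))

    def draw(n: int, gc: float) -> np.ndarray:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        return bases[rng.choice(4, size=n, p=p)]

    length = 2 * _MARGIN + n_origins * _SPACING
    seq = draw(length, background_gc)
    from .acs_alignment import revcomp

    acs_list: list[AcsAnnotation] = []
    for i in range(n_origins):
        acs = _MARGIN + i * _SPACING  # 1-based start of the planted motif
        core_lo = acs - 1 - at_core_len // 2
        seq[core_lo : core_lo + at_core_len] = draw(at_core_len, core_gc)
        strand = "W" if rng.random() < 0.5 else "C"
        planted = motif if strand == "W" else revcomp(motif)
        seq[acs - 1 : acs + 14] = list(planted)
        acs_list.append(
            AcsAnnotation(f"syn{i:04d}", _CHROM, acs, strand, "synthetic")
        )

    text = "".join(seq)
    rc = revcomp(motif)
    for a in acs_list:
        for _ in range(max_redraws):
            lo = max(a.acs_start - 1001, 0)
            hi = min(a.acs_start + 1014, length)
            window = text[lo:hi]
            n_hits = window.count(motif) + (window.count(rc) if rc != motif else 0)
            if n_hits <= 1:
                break
            # redraw the background around the planted motif
            pre = draw(a.acs_start - 1 - lo, background_gc)
            post = draw(hi - (a.acs_start + 14), background_gc)
            planted = text[a.acs_start - 1 : a.acs_start + 14]
            text = text[:lo] + "".join(pre) + planted + "".join(post) + text[hi:]
        else:
            raise RuntimeError(
                f"{a.origin_id}: motif not locally unique after {max_redraws} redraws"
            )
    return {_CHROM: text}, acs_list


def generate_features_and_timing(
    acs_list: list[AcsAnnotation],
    tss_offsets=DEFAULT_TSS_OFFSETS,
    gene_end_offsets=DEFAULT_GENE_END_OFFSETS,
    tss_prob: float = 107 / 222,
    gene_end_prob: float = 152 / 222,
    early_rule=None,
    trep_early: tuple[float, float] = (20.0, 3.0),
    trep_late: tuple[float, float] = (35.0, 4.0),
    offset_jitter: float = 0.0,
    seed: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[FeatureRecord], list[TimingRecord], dict[str, dict]]:
    """Plant TSS/gene-end features at oriented offsets and draw timing.

    Each origin receives a TSS (gene end) with probability ``tss_prob``
    (``gene_end_prob``) at an offset drawn from the given oriented
    offsets, translated to genomic coordinates through the origin's
    orientation.  ``early_rule(has_tss)`` maps context to the Bernoulli
    probability of being HU-early; the default gives TSS-proximal origins
    p = 0.47 and solves the remaining rate so the overall proportion is
    0.39.  Trep minutes are drawn from Gaussian early/late distributions
    (clipped at 5 min).

    Returns the feature table, the timing table, and a per-origin record
    of what was planted.
    """
    rng = np.random.default_rng(seed)
    if early_rule is None:
        p_tss = 0.47
        overall = 0.39
        p_other = (overall - p_tss * tss_prob) / max(1.0 - tss_prob, 1e-12)
        p_other = min(max(p_other, 0.0), 1.0)

        def early_rule(has_tss: bool) -> float:
            return p_tss if has_tss else p_other

    features: list[FeatureRecord] = []
    timing: list[TimingRecord] = []
    placed: dict[str, dict] = {}
    warned = 0
    for a in acs_list:
        rec: dict = {"tss": [], "gene_end": []}
        for kind, offsets, prob in (
            ("TSS", tss_offsets, tss_prob),
            ("gene_end", gene_end_offsets, gene_end_prob),
        ):
            if rng.random() >= prob:
                continue
            off = float(offsets[rng.integers(len(offsets))])
            if offset_jitter > 0:
                off += rng.normal(0.0, offset_jitter)
            off = int(round(off))
            coord = a.acs_start + a.orientation * off
            clen = None if chrom_lengths is None else chrom_lengths.get(a.chrom)
            if coord < 1 or (clen is not None and coord > clen):
                warned += 1
                continue
            features.append(FeatureRecord(kind, a.chrom, coord, a.t_rich_strand))
            rec["tss" if kind == "TSS" else "gene_end"].append(off)
        has_tss = bool(rec["tss"])
        early = bool(rng.random() < early_rule(has_tss))
        mu, sd = trep_early if early else trep_late
        trep = float(max(rng.normal(mu, sd), 5.0))
        timing.append(TimingRecord(a.origin_id, early, trep))
        rec["early"] = early
        rec["trep"] = trep
        placed[a.origin_id] = rec
    if warned:
        import warnings

        warnings.warn(f"{warned} feature(s) fell outside the chromosome; skipped")
    return features, timing, placed
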