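# Methods

This note documents the models and numerical choices behind `orichrom`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the known limitations.

## Coordinate conventions

All genomic coordinates are 1-based inclusive; BED exports are 0-based
half-open. The alignment anchor of an origin is `acs_start`, the minimum
of the 15-bp proACS start/end coordinates (the T residue at position 1
of the T-rich strand). SGD origin calls are 11 bp long; subtracting 2
from the minimum of their start/end gives the 15-bp proACS start.
Relative position 0 on the aligned grid is the probe nearest
`acs_start`, ties broken toward the lower genomic coordinate (the choice
between the equidistant left and right probe is otherwise arbitrary).
Positive positions point 3′ on the T-rich strand (toward the B1
element); origins whose T-rich strand is the Crick strand have their
position axis reflected. Reflection is an involution, and on a
strand-balanced population with symmetric architecture the average
profile is symmetric — both are tested properties.

## ACS-aligned matrix

Probes within ±800 bp of the ACS are snapped onto a 4-bp relative grid
(401 slots). A slot takes the probe whose coordinate lies within 2 bp of
the slot center; the nearest probe wins and ties go to the lower
coordinate; slots without such a probe are NA. No imputation is
performed at this stage — the NA fraction of the matrix equals the
fraction of grid slots lacking a probe.

Origin lists are filtered before alignment: at least 800 bp of flanking
sequence on both sides of the ACS; at most 9 duplicated probe sequences
in the 800-bp region centered on the ACS (the duplicated-probe flags are
supplied as a sidecar column derived from the array design — binary
array-design files are not parsed); for 1-bp-resolution in-vitro tracks,
at most 40 missing calls among the 801 positions of the central 800-bp
region. De-duplication of curated vs SGD origin calls treats entries
within 50 bp on the same chromosome as the same origin and keeps the
curated entry; the tolerance is configurable because exact-coordinate
equality is too strict across coordinate adjustments.

## Smoothing

All smoothing is LOESS (locally weighted linear regression, tricube
weights, no robustness iterations), with the span expressed as a probe
count: the fit at each position uses the `span` nearest non-NA
neighbours (`frac = span / n_non-NA` in the underlying statsmodels
lowess). Local linear fits reproduce constants and straight lines
exactly, which is tested. Average profiles for display use a span of 36
probes; the calling pipeline smooths per-origin rows with a span of 11
probes — wide enough to suppress per-probe noise (SD shrinks roughly by
√span), short enough (±~22 bp reach) not to displace occupancy peaks or
drag the deep NDR trough into the flanking maxima. Peak-to-peak geometry
on a 200-origin average uses the short span for the same reason: with
that many origins the average is already low-noise, and a 36-probe span
measurably depresses the +1/−1 peaks next to the trough.

## NDR geometry

The average profile's NDR is measured peak-to-peak: the interior maxima
of the smoothed profile inside search windows −400..−40 and +40..+400 bp
are taken as the −1/+1 nucleosome midpoints; width is their separation
and center their midpoint. The windows exclude the trough itself and
distal nucleosomes; a window whose maximum falls on its boundary has no
interior peak and is an error (e.g. a monotone profile). The
nucleosome-free span of a width-`w` NDR is `w − 146` bp, subtracting the
two 73-bp inner halves of the flanking nucleosomes.

## Per-origin nucleosome calling

Each origin row is scanned with a sliding 26-probe Pearson correlation
against side-specific flank templates; local maxima of the correlation
track with score ≥ 0.45 become nucleosome midpoints. Numerical choices:

- **Window layout.** A 26-probe window has no central probe; the right
  template places 12 probes before its center and 13 after, the left
  template the mirror image, so a symmetric profile yields exactly
  mirrored templates and neither side acquires a half-probe offset.
- **Template estimation.** `build_flank_templates` cuts the windows from
  the average profile around its flanking maxima. When NDR widths are
  heterogeneous the grand average is smeared and nearly flat there, so
  the pipeline default (`build_flank_templates_from_matrix`) estimates
  each side's template by peak-aligned averaging: the 26-probe window
  centered on each smoothed row's flanking maximum, averaged over
  origins. For homogeneous origins the two constructions coincide.
  Window centers are picked on smoothed rows; centering windows on raw
  noisy rows selects for upward noise and puts a spike artifact at the
  template center.
- **NA handling.** A window needs ≥ 20 of 26 non-NA overlapping probes
  for a valid correlation; zero-variance windows are NA. NA positions
  break the track into runs; maxima are strict, plateaus collapse to
  their center.
- **Non-maximum suppression.** Correlation ridges under noise split into
  micro-maxima. Calls closer than 120 bp are physically implausible
  (a nucleosome core spans 147 bp), so among maxima within 120 bp the
  highest correlation wins.
- **Side assignment.** The left template scores positions < 0, the right
  template positions ≥ 0; a call at position 0 belongs to the right
  side. NDR width is (smallest midpoint > 0) − (largest midpoint < 0);
  an origin missing a call on either side has undefined width and is
  excluded from width distributions.

Width distributions use a 9-probe (36 bp) moving sum over the 4-bp width
grid, then LOESS smoothing. The histogram underlying the moving sum
conserves the number of widths; each interior width contributes to
exactly 9 moving windows.

## Sequence features

Dinucleotide property profiles score each 75-bp window (74 overlapping
dinucleotides) by summing property values over dinucleotide counts and
dividing by the number of unambiguous dinucleotides; the value is
assigned to the window's central probe. Dinucleotides containing N are
excluded from numerator and denominator. Sequences are taken on the
oriented (T-rich 5′→3′) strand with a 37-bp margin so every grid probe
gets a full window; GC content uses the same 75-bp window. Average
profiles are rescaled linearly to [−1, 1] (an error for constant input),
LOESS-smoothed with a 76-bp span, restricted to −372..+424 bp, and
grouped by seeded k-means (single initialization, iteration cap 10,000,
tol 0 so the cap is the only stopping rule). Each group's mean profile
is correlated with the average occupancy profile, interpolated onto the
same grid when the grids differ.

## Origin clustering

Origins are clustered on raw log2 values (no per-row z-scoring) over
−372..+424 bp. NA cells are imputed with the positional mean for the
distance computation only; reported sub-cluster mean profiles are
averages of the raw values. Cluster labels are arbitrary — evaluations
compare partitions (adjusted Rand index), never labels. The inter-group
Pearson correlation matrix and its maximum off-diagonal are reported so
the number of groups can be chosen by the distinctness criterion;
the choice of k is left to configuration.

## Context and timing

Feature distances are signed along the oriented origin axis:
`(feature − acs_start) × orientation`. Feature distributions within
±800 bp use a 25-probe moving-sum count centered on the window midpoint,
LOESS-smoothed with a 26-probe span. Windowed timing statistics (early
origin proportion, mean Trep in minutes) gather the origins with a TSS
or gene end in each 25-probe window and are masked when fewer than 5
origins contribute. Trep assignment takes the timing data point nearest
the ACS, ties to the lower coordinate.

The resampling test draws 10,000 same-sized origin groups **without
replacement** from the full origin set and reports the percentage whose
early proportion falls strictly below the observed subset's proportion —
one-sided, in the direction of the observed deviation. On enumerable
instances this converges to the hypergeometric tail probability, which
serves as the independent oracle in tests. NDR-width quantiles sort the
width-defined origins (stable sort; ties keep input order, i.e. go to
the lower bin) and split them into 7 groups whose sizes differ by at
most one; each bin's early proportion is scored against resamples from
the full origin set.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
in log2 space directly (there is no attempt to simulate MNase digestion
or hybridization physics):

- **Occupancy.** Each origin is a sum of Gaussian bumps (amplitude 1.0,
  SD 50 bp — a ~147-bp core seen through 4-bp probes and array
  smoothing) at planted midpoints, minus a raised-cosine central
  depletion (depth 1.5). The innermost midpoints sit exactly at
  center ± width/2; widths are uniform on [160, 500] bp by default.
  Flanking arrays continue outward at a 165-bp period (147-bp core +
  linker) with positional jitter whose SD grows 20 bp per step, so
  distal peaks smear and average peak-to-trough height decays with
  distance, as on real chromosomes; arrays extend one period beyond the
  probe window so in-window nucleosomes always have neighbours. The
  depletion's support ends 73 bp (a nucleosome midpoint-to-inner-edge
  distance) inside the innermost midpoints, so the trough lies strictly
  between the flanking cores and the observable flanking maxima coincide
  exactly with the planted midpoints — the recorded truth is
  self-consistent. Probe noise is Gaussian (SD 0.2 default); missing
  probes (5%) and duplicated-probe flags (2%) are injected at stated
  rates; strands are assigned at random.
- **Genome.** Random background sequence (GC 0.38, as in yeast) with one
  T-rich 15-mer ACS motif per origin planted inside a 150-bp AT-rich
  core (GC 0.10); the motif strand is randomized and the local
  background redrawn until the motif is unique within ±1 kb.
- **Features and timing.** TSSs are placed at oriented offsets −276,
  +112 and +328 bp (48% of origins) and gene ends at −420/+240 bp (68%),
  translated through each origin's orientation. Early-in-HU flags are
  Bernoulli with probability 0.47 for TSS-proximal origins and the
  complement rate that makes the overall proportion 0.39; Trep is drawn
  from N(20, 3) minutes for early and N(35, 4) for late origins,
  clipped at 5.

Every generator is deterministic given a seed.

**What passing tests show — and what they do not.** The generator
produces idealized Gaussian-bump chromatin with homogeneous amplitudes,
a single nucleosome repeat length, uncorrelated Gaussian probe noise and
uniformly random missingness. Real tiling-array data have
sequence-dependent probe affinities, correlated noise, fragment-length
effects, copy-number artifacts and genuine biological heterogeneity
(fragile or absent flanking nucleosomes, overlapping promoter NDRs).
Recovery of planted architecture therefore validates the estimators'
correctness and resolution, not their robustness to every real-data
pathology.

## Known limitations

- Template correlation inherits a small systematic bias where the local
  window's shoulder structure differs from the averaged template's: the
  innermost calls sit up to ~2 bp outside the true midpoints. On the
  4-bp grid this occasionally rounds a call one probe outward, so a few
  origins per several hundred can exceed the one-probe error bound on
  unlucky noise realizations.
- Peak-to-peak NDR measurement automates what was historically a visual
  selection of the flanking maxima; its search windows (±40..±400 bp)
  assume the NDR trough is narrower than 80 bp of the anchor and the
  +1/−1 peaks lie within 400 bp.
- The bivariate histogram uses rectangular bins (a hexagonal-binned
  display is a plotting nicety; no downstream statistic depends on bin
  shape).
- Resampling is without replacement; with-replacement bootstrap
  percentiles would differ slightly for small origin sets.
- Genome-build reconciliation beyond motif re-localization
  (`locate_acs`) is out of scope; timing tracks are matched by nearest
  coordinate.
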