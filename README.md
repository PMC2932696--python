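# orichrom

Chromatin structure at DNA replication origins, analyzed the way promoter
chromatin is analyzed at transcription start sites: by aligning every
origin on a single functional element and orienting all of them the same
way.

In budding yeast, every replication origin contains a 15-bp, T-rich ARS
consensus sequence (ACS) bound by the origin recognition complex (ORC).
Because origins are intrinsically asymmetric — the B1 element lies 3′ of
the ACS on the T-rich strand — anchoring tiling-array nucleosome
occupancy at the ACS T residue and orienting each origin T-rich 5′→3′
produces high-resolution maps of the nucleosome-depleted region (NDR) and
the phased nucleosome arrays that flank it.

`orichrom` implements that analysis end to end for anyone studying
origin chromatin on 4-bp tiling-array occupancy tracks (or 1-bp in-vitro
maps):

- **ACS curation & alignment** — locate 15-bp proACS motifs in a genome,
  reconcile curated and SGD origin calls (`min(start, end) − 2` converts
  SGD's 11-bp call to the 15-bp proACS), filter origins by flanking
  coverage, duplicated probes, and missing calls, and build the
  origins × positions matrix (±800 bp, 4-bp grid, oriented by the T-rich
  strand).
- **Occupancy profiles** — per-position averages with LOESS smoothing,
  bivariate histograms as 2-D error bars, condition difference profiles
  (e.g. ORC depletion vs wild type), and peak-to-peak NDR geometry. The
  nucleosome-free span of an NDR of width `w` is `w − 146` bp (the inner
  halves of the two flanking nucleosomes cover 2 × 73 bp).
- **Nucleosome calling** — per-origin midpoints from sliding 26-probe
  Pearson correlation against templates cut around the flanking
  occupancy maxima, with a 0.45 correlation cutoff; per-origin NDR width
  is the distance between the ACS-proximal calls on either side.
- **Sequence features** — windowed GC content and 75-bp-window
  DiProDB-style dinucleotide property profiles on the oriented strand,
  rescaled to [−1, 1] and grouped by k-means.
- **Origin clustering** — k-means on the two-nucleosome region
  (−372..+424 bp) with inter-cluster profile correlations.
- **Context & timing** — oriented distances to TSSs, gene ends,
  centromeres and telomeres; 25-probe moving-sum feature distributions;
  windowed early-origin proportions and mean replication times (Trep),
  masked below 5 origins; NDR-width quantiles scored against 10,000
  resampled origin groups.
- **Synthetic data** — a seeded generator that plants origins with known
  NDR widths, phased flanking arrays with positional decay, ACS motifs
  in AT-rich cores, TSS/gene-end offsets, and early/late timing labels,
  so the whole pipeline is testable with full ground truth and no
  downloads.

## Worked example

Two hundred synthetic origins are planted with the canonical architecture
(276-bp peak-to-peak NDR, 165-bp nucleosome period, probe noise
SD 0.2 log2 units, 5% missing probes), aligned, and measured:

```python
import numpy as np
import orichrom as oc

arch = oc.ArchParams(width_low=276, width_high=276, noise_sd=0.2,
                     na_fraction=0.05, dup_fraction=0.0)
tracks, acs_list, truths = oc.generate_occupancy(200, arch, seed=1)

matrix = oc.build_aligned_matrix(tracks, acs_list)
profile = oc.average_profile(matrix, smooth=True, span_probes=11)
geom = oc.peak_to_peak_ndr(profile)
print(f"average NDR width : {geom.width:.0f} bp (peaks {geom.left_pos:+d}/{geom.right_pos:+d})")
print(f"free DNA          : {oc.free_dna_span(geom.width):.0f} bp")

calls, widths = oc.call_pipeline(matrix)
defined = [w for w in widths.values() if w is not None]
err = np.median([abs(widths[t.origin_id] - t.ndr_width)
                 for t in truths if widths[t.origin_id] is not None])
print(f"per-origin widths : {len(defined)}/200 defined, median {np.median(defined):.0f} bp")
print(f"median |error|    : {err:.1f} bp vs planted truth")
```

```
average NDR width : 276 bp (peaks -136/+140)
free DNA          : 130 bp
per-origin widths : 200/200 defined, median 276 bp
median |error|    : 4.0 bp vs planted truth
```

The average profile's flanking maxima sit one probe either side of
±138 bp, so the measured peak-to-peak width reproduces the planted
276 bp; subtracting the 146 bp inside the two flanking nucleosomes
leaves ~130 bp of nucleosome-free DNA. Per-origin template calling
recovers every planted width to within a probe or two even at this noise
level.

The same pipeline is available from the shell:

```sh
orichrom simulate --n-origins 200 --seed 1 --out sim/
orichrom align    --tracks sim/tracks.tsv --acs sim/acs.tsv --out matrix.tsv
orichrom profile  --matrix matrix.tsv --out profile.tsv
orichrom call     --matrix matrix.tsv --out calls.tsv --bed calls.bed --acs sim/acs.tsv
orichrom cluster  --matrix matrix.tsv --k 4 --seed 1 --out clusters.tsv
orichrom timing   --acs sim/acs.tsv --features sim/features.tsv \
                  --timing sim/timing.tsv --out timing.tsv
```

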