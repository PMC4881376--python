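# Methods

This note documents the models, algorithms, defaults and design choices
behind `isophene`, and what the synthetic benchmarks do and do not show.

## Problem setting

A multi-isotope SIP experiment amends an environmental sample with several
isotopically enriched substrates; NanoSIMS then images the sample at up to
seven masses in parallel. After accumulating ion counts over the pixels of
each single-cell ROI, every cell is summarized by five ratios used for
clustering — ¹³C/¹²C, ¹⁵N¹²C/¹⁴N¹²C, ³³S/³²S, C/CN, S/CN — plus ³⁴S/³²S
kept for completeness. Cells with similar ratio profiles are grouped into
*isotope phenotypes*; gradients between phenotypes arise from differences
in substrate uptake, growth rate, storage-compound content and
cross-feeding of labeled metabolites. FISH taxon labels, where available,
provide an independent check of whether phenotypes track phylogeny.

## Preprocessing

* **Dead-time correction.** Pulse-counting detectors are blind for τ after
  each ion; measured counts are corrected per pixel, plane and channel as
  `n / (1 − (n/t_dwell)·τ)`. Default τ = 44 ns, a typical NanoSIMS
  electron-multiplier value; it is configurable because the true constant
  is instrument-specific. The correction is applied per plane, before
  accumulation, because it is rate-based and plane rates differ. Pixels
  with rate·τ ≥ 1 raise a saturation error naming the pixel.
* **Plane alignment.** Integer-pixel shifts only, estimated per plane by
  maximizing FFT cross-correlation with plane 0 of the ¹⁴N¹²C⁻ channel
  (the biomass channel, which carries the most structure), searched within
  ±`max_shift` (default 10 px). Sub-pixel alignment is deliberately
  avoided: interpolation would corrupt count statistics.
* **Accumulation.** Shifted planes are summed over the region covered by
  every plane; out-of-overlap pixels are zeroed. With zero shifts the sum
  is exact, conserving counts channel by channel.
* **ROI extraction.** Hand-drawn masks are ingested as label images; the
  automated alternative thresholds the accumulated ¹⁴N¹²C⁻ image (Otsu by
  default), groups foreground by 8-connectivity, discards components
  smaller than `min_area_px` (default 20 px) and labels survivors in
  raster-scan order.
* **Tabulation.** Per-ROI, per-channel sums over member pixels, with
  unweighted pixel centroids (0-based, x = column) and √N Poisson
  uncertainties as annotation columns.

## Isotope arithmetic

Ratios are always computed from ROI-summed counts, never as means of
per-pixel ratios (the latter is biased at low counts). Rows with any zero
denominator are dropped with a logged reason, not zero-filled: a cell with
no CN signal is not a cell measurement.

Reference ratios default to VPDB ¹³C/¹²C = 0.0112372, atmospheric
¹⁵N/¹⁴N = 0.0036765, VCDT ³³S/³²S = 0.0078772 and ³⁴S/³²S = 0.0441626;
all are overridable. Conversions: R = R_ref(1 + δ/1000); atom fraction
F = R/(1+R), using the two-isotope approximation for sulfur as well
(³⁴S, ³⁶S neglected in F₃₃), which matches the single-ratio use throughout.

Instrumental fractionation is corrected multiplicatively:
`corrected = measured × (true_std / measured_std)` per ratio column, with
a standard of known composition (e.g. EA-IRMS-measured spores). By default
only ¹³C/¹²C and ¹⁵N/¹⁴N carry standards; sulfur ratios pass through,
since spore standards contain too little sulfur for a reliable correction.
Both corrected and uncorrected ratio tables are first-class
(`attrs["corrected"]`), because either convention may be wanted in reports.

## Clustering

All ten algorithms are implemented from scratch (scikit-learn and scipy
appear only as test oracles):

* **Hierarchical** (single, complete, average, McQuitty/WPGMA, centroid/
  UPGMC, median/WPGMC, Ward) via the Lance–Williams recurrence. Centroid,
  median and Ward operate on squared Euclidean distances (the Ward variant
  whose merge order matches the D2 convention); the others on Euclidean
  distances. Merge ties break toward the lowest pair index. Cutting at k
  undoes the last k−1 merges — for the non-monotone linkages (centroid,
  median can produce inversions) this is a deliberate, documented choice.
* **PAM**: greedy BUILD then exhaustive SWAP to a local optimum;
  deterministic given data order. On small instances SWAP reaches the
  global optimum (verified by enumeration in tests).
* **k-means**: Lloyd iterations, k-means++ seeding, best of `restarts`
  (default 20) by within-cluster sum of squares; empty clusters repaired
  by reassigning the farthest point.
* **Fuzzy c-means**: Bezdek alternating optimization of
  J = Σᵢⱼ u_ij^m ‖xᵢ−cⱼ‖², fuzzifier m = 2 (the common default of the
  standard R implementation), tol = 1e−6 on max|Δu|, max 500 iterations,
  20 restarts, random membership initialization from the seed. A point
  coincident with a center gets full membership there. Hard labels are
  argmax memberships; hardening that empties a cluster marks the cell
  invalid in scans.

Features are z-scored per column by default — the five ratios span an
order of magnitude, so unscaled Euclidean distances would be dominated by
C/CN — and the scaling is recorded so centers can be reported in raw ratio
space. The CH index and silhouette widths follow their standard
definitions; CH for fuzzy solutions is computed on hardened labels, since
the index is defined for partitions. The (method × k) scan evaluates CH
for every cell over k = 2..10, breaking ties toward smaller k and then
method name.

## Phenotyping

Cluster indices from any single run are arbitrary. Canonical phenotype
names (*a*–*e*) are assigned by minimum-cost one-to-one matching
(Hungarian algorithm) between the solution's centers and named archetype
centers, both expressed in the current feature scaling. The default
archetypes are the day-7 per-phenotype mean ratios; matching against fixed
archetypes makes labels reproducible across runs, ratio subsets and
conditions. Summary tables use sample standard deviations (n−1);
cross-tabulations count unmatched ROIs under taxon `unknown`. The
ratio-subset comparison clusters each subset with identical method/k/seed,
canonicalizes each against the archetypes restricted to the subset's
columns, and counts ROIs whose canonical label is identical across all
subsets — consistency is monotone non-increasing as subsets are added.
One subset in the default menu pairs the carbon and sulfur isotope ratios
with both elemental ratios (named "13C+33S+C/S": their quotient is the
cellular C/S).

## Synthetic data

The generator's components are the per-condition phenotype summaries built
into `presets.py`: ROI counts, per-ratio means and standard deviations for
five conditions (2, 7, 10 days; unlabeled control; killed control),
totalling 3115 ROIs. Each component is a *diagonal* Gaussian in 6-dim
ratio space — only per-ratio spreads are available, no covariances — with
draws at or below `ratio_floor` = 1e−6 rejected and resampled (clipping
would create a point mass that distorts cluster shapes). ³⁴S/³²S, absent
from the summaries because ³⁴S was not a tracer, defaults to the VCDT
natural-abundance value 0.0442 with a 10% spread. Taxon labels follow the
observed per-phenotype FISH composition (a/b/c: 86/98/92% gamma; d: 85%
gamma, 15% unknown; e: 68% delta, 32% unknown); the same mixes are applied
to every condition, an approximation since per-condition compositions are
not separately available. Morphologies: a–c filaments, d cocci, e rods.

Count-level realizations invert the ratio definitions at a chosen CN total
(nc14 = CN/(1+r15N), C = rC_CN·CN split by r13C, S = rS_CN·CN split by
r33S/r34S with ³²S the remainder) and draw each channel as an independent
Poisson variate. Image-level scenes place non-overlapping cells with the
component's morphology, spread the expected channel counts uniformly over
the cell's pixels and planes, add a uniform background rate, and emit
independent Poisson planes with optional integer stage drift
(periodic-boundary shifts; cells are kept away from edges by a margin).

The per-condition spreads are treated as *total* spread at the ratio
level; the count-level path adds Poisson noise on top, which is only
realistic when used with lower CN totals than the defaults.

### What the benchmarks show — and a known negative result

Because the generator is faithful to the printed summaries but ignorant of
the real data's correlation structure, recovery benchmarks measure the
method, not the original measurements. On the day-7 mixture (777 cells,
components 443/136/106/32/60):

* k-means (k = 5) recovers all five components nearly perfectly, and a CH
  scan that includes k-means selects k = 5.
* Fuzzy c-means with m = 2 recovers components b, c, e well (marker-
  dimension centers within a few percent) but its *global* optimum splits
  the dominant low-enrichment component a and absorbs the small
  high-S/CN component d (n = 32): the matched "d" center's S/CN lands
  near 0.09 instead of 0.31, and an FCM-only CH scan favors k = 4. This
  was verified not to be an optimizer artifact — the component-aligned
  configuration is a valid FCM fixed point with a strictly *higher*
  objective. It reflects the known tendency of m = 2 fuzzy c-means toward
  balanced clusters on diagonal-Gaussian mixtures with a 14:1 size
  imbalance; on the real measurements, correlations between ratios
  evidently sharpened these clusters enough for FCM to resolve all five.
  The corresponding acceptance-level tests assert the stated recovery
  tolerances and are expected to fail under these study conditions; they
  are kept unweakened as an honest record.

## Numerical choices

* Ties break toward the lowest index everywhere (merges, argmax labels,
  scan cells); randomness only via explicit seeds (`numpy` Generator).
* Fuzzy memberships are renormalized to sum to 1 within 1e−9; distances
  are floored at 1e−300 before inversion.
* Acceptance-script problem sizes: one 777-ROI day-7 realization for the
  center-recovery experiment; ten realizations for the scan vote; the full
  five-condition census (3115 ROIs) for the ROI count.

## Limitations

* No QSA correction, detector relative-sensitivity calibration or
  sub-pixel drift modeling; CAMECA `.im` and Look@NanoSIMS `.mat` session
  files are not parsed (the import path is exported tables/TIFFs).
* Diagonal-covariance components; no label-uptake kinetics; no
  within-cell substructure (sulfur granules) in scenes.
* FISH labels are ingested as pre-registered tables; image registration
  between fluorescence and ion images is out of scope.
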