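# Methods

## Morphometry

Objects enter as 2D integer label masks (0 = background) or as
pre-computed object tables. Per object:

* **Area** = pixel count × pixel_size². Pixel indices are 0-based; the
  centre of pixel (i, j) maps to ((j + 0.5)·ps, (i + 0.5)·ps) µm.
* **Moment-equivalent ellipse axes** come from the covariance matrix of
  the pixel centres plus the "pixel as unit square" correction of
  1/12 px² on each diagonal term; full axis lengths are 4·√λ. The
  correction makes a solid w×h rectangle score aspect ratio exactly
  min(w,h)/max(w,h) and keeps single-pixel objects non-degenerate
  (both axes 4·√(1/12) px). Aspect ratio = short/long ∈ (0, 1];
  1 is perfectly round.
* **Feret diameter** is the maximum pairwise distance between pixel
  *centres*, computed on the convex hull (scipy `ConvexHull`, brute
  force for ≤ 3 or collinear points). It is not extended to pixel
  corners; a single-pixel object has Feret 0. This convention is exactly
  reproducible by an all-pairs scan, which the tests exploit.
* **Size filter**: objects with area in [0.01, 2.1] µm² are retained,
  boundaries inclusive (the exclusion rule is "smaller/larger than").
* **Nearest-neighbour distance** is the minimum centroid-to-centroid
  Euclidean distance within the same tile (scipy `cKDTree`). Cross-tile
  neighbours are ignored, which biases distances upward for objects near
  tile edges; with ~10–23 objects per 100 µm² tile the effect is small
  but users comparing against whole-ROI analyses should be aware of it.
  A tile with a single object gets no distance and a warning.
* **Tile aggregation** sums retained-object count and total area per
  tile. Filtering commutes with aggregation. Normalisation divides by
  the pooled control mean (one scalar per metric, layers pooled).

Objects touching the image edge are retained; edge exclusion applies to
segmentation training upstream, not to analysis.

## Hierarchical bootstrap

Groups are genotype × layer cells. One repetition draws, all with
replacement: `n_animals` animals within the genotype, `n_sections`
sections per drawn animal, `n_tiles` tiles per drawn section restricted
to the group's layer, and — for the per-object area metric — `n_mitos`
objects per drawn tile. The repetition's statistic is the median of the
pooled values (tile counts, or object areas). Defaults are 3 × 3 × 50
(× 100), i.e. 450 tiles and 45,000 objects per repetition, 10,000
repetitions for final runs and 1,000 for calibration runs. A section
with fewer tiles than `n_tiles` is simply oversampled; tiles with zero
objects are excluded from the area metric's tile pool (an empty tile
cannot contribute objects) but kept for the count metric.

**Randomness and pairing.** A master seed spawns one `SeedSequence`
substream per repetition; repetition r re-seeds an identical generator
for every group (common random numbers). Results are therefore
bit-reproducible for a given (dataset, config, seed) and the
per-repetition medians of two groups form a paired sample, which is what
makes the joint distribution and P_boot meaningful per repetition and
also reduces the variance of paired comparisons.

**P_boot and joint distributions.** P_boot(A > B) is the fraction of
repetitions with median_A > median_B, ties counted ½ — so
P_boot(A,B) + P_boot(B,A) = 1 exactly. Ties are common for the count
metric because medians of integer counts land on a half-integer grid.
The joint distribution is an equal-width 2D histogram over the pooled
range of both median arrays — 10 bins per axis for counts, 100 for
areas — normalised to total mass 1; a zero range degenerates to a
single diagonal bin.

**Interpretation.** Under a true null the per-seed P_boot behaves like a
p-value: approximately uniform on (0, 1), with only its expectation
pinned at ½. Calibration claims therefore concern the mean over many
independent datasets, not a single run; the tests average over 20–50
seeds. With three animals per group and multiplicative animal
variability of CV 0.15, a count effect of 19 → 23 (log-effect 0.19
against a between-group animal-median SD of ≈ 0.12) is recovered with
P_boot ≥ 0.85 in only ~60–70% of simulated studies — the realized
animals fully reverse the ordering in roughly 9% of draws. This is a
property of the design (3 animals), not of the estimator; the median
P_boot across seeds (~0.9) matches what a single well-behaved study
reports.

**Sampling-size calibration.** `sampling_size_test` reruns the bootstrap
`n_runs` times per candidate size (defaults {20, 32, 50} tiles,
{5, 10, 20, 50, 100} objects; 1,000 repetitions) and reports two
variability measures: `rep_median_sd`, the within-run spread of the
resampled medians (the width of the bootstrap distribution itself),
and `grand_median_sd`, the across-run SD of each run's grand median.
Oversampling tiles shrinks `rep_median_sd` monotonically (measured
1.07 → 1.04 → 1.01 counts for 20/32/50 tiles on default synthetic
data). `grand_median_sd` is reported for completeness but is a poor
discriminator for the count metric: grand medians snap to the
half-integer grid, so its 10-run estimate is dominated by quantisation
noise.

## Plasticity scoring

Recordings are evoked FP peak-amplitude series at a nominal 0.1 Hz with
per-sample phase markers (pre / conditioning / post; 10 min pre and
60 min post, conditioning carries no analysed samples).

* **Baseline gate**: OLS line through all pre samples; discard if
  r² > 0.2. A zero-variance (flat) baseline has undefined OLS r²; it is
  defined here as 0 (pass).
* **Post/pre ratio**: mean of the last 5 min of post over the last 5 min
  of pre (30 samples each at 0.1 Hz; windows are selected by time, so
  irregular sampling still gets the final 300 s). The significance of
  the change is a Welch two-sample t comparison of the two windows at
  α = 0.05; the paired/unpaired and raw/normalised choices are not
  dictated by convention, so the unpaired Welch test on raw amplitudes
  was chosen (normalisation by a constant would not change it).
* **Classification**: LTD iff ratio < 0.90 and p < 0.05; LTP iff
  ratio > 1.10 and p < 0.05; otherwise no change. The rule is monotone
  in the ratio at fixed significant p. Note that an injected +8% effect
  sits ~0.7 standard errors below the +10% band edge at 10% per-sample
  noise, so a minority (~25%) of such experiments legitimately classify
  as weak LTP; tests assert the majority behaviour.
* **Time plots**: amplitudes divided by the mean of the whole pre phase,
  averaged in consecutive 6-sample (1-min) blocks separately within pre
  and post; a trailing partial block averages the samples it has.
* **Input/output curves**: half-max amplitude = max response / 2;
  half-max intensity from piecewise-linear interpolation at the first
  crossing (exact sample hits returned directly); an error if the curve
  never crosses half-max.

## Synthetic data

The generator reproduces the study design: 2 genotypes × 3 animals ×
3 sections × 3 layers (SO, SR, SLM) × 30 tiles of 10 × 10 µm.

* **Counts** per tile are negative binomial (mean m, dispersion k = 10;
  variance m + m²/k). Default means are the reported per-layer medians:
  CTL 10/10/19 and cKO 13/13/23 (SO/SR/SLM) per 100 µm² — the
  knockout is more numerous in every layer, most so in SLM.
* **Areas** are log-normal (log-SD 0.6, right-skewed) truncated to the
  size filter via inverse-CDF sampling, so every generated area respects
  [0.01, 2.1] µm² by construction; a median outside the filter raises.
  Only normalised areas are reported by the source data, so absolute
  anchors are package choices: CTL SR median 0.20 µm², SLM 30% larger
  (larger distal mitochondria), and a uniform cKO/CTL ratio of 0.90
  (smaller knockout mitochondria). All are configurable.
* **Aspect ratios** are Beta on (0, 1]: (6, 2.5) in SO (rounder,
  mean ≈ 0.71) and (4, 3) in SR/SLM (mean ≈ 0.57), identical across
  genotypes (no genotype effect on shape).
* **Random effects**: multiplicative log-normal factors with mean 1,
  CV 0.15 per animal and 0.10 per section, drawn independently for the
  count and area channels and shared across that animal's/section's
  layers. Neither CV is constrained by reported data; both are exposed
  in `GeneratorParams`. `GeneratorParams.null()` gives both genotypes
  the CTL parameters for calibration experiments.
* **Masks** render each object as a filled rotated ellipse matching its
  area and aspect ratio (pixel-centre-in-ellipse test at 0.02 µm/px by
  default); overlaps are resolved by redrawing positions up to 100
  times, then an error names the object. The ground-truth table enables
  round-trip tests: rendered objects ≥ 100 px recover area within 5%
  and aspect ratio within 0.1 through `compute_object_metrics`.
* **FP recordings**: i.i.d. Gaussian amplitudes (CV 0.10) around a
  100 µV baseline, ×(1 + effect) after conditioning; 60 pre and 360
  post samples at 0.1 Hz, clipped at zero.

What the generator does **not** emulate: spatial clustering of objects
within tiles (centroids are uniform), correlations between area and
count within a tile, segmentation errors (merged/split/missed objects),
EM texture, within-trace drift or artifacts in FP recordings. Passing
tests therefore validate the estimators under the assumed generative
law, not robustness to segmentation or recording pathology.

## Reporting

Percent change is 100·(CTL − cKO)/CTL, displayed rounded to the nearest
integer with the raw value retained. The variance-ratio test puts the
larger sample variance in the numerator and doubles the F upper-tail
probability (two-sided, df = n−1 each). Line profiles are binned in
consecutive 10-µm bins from the first sampled position, with zero-valued
(out-of-image) samples removed before averaging; the peak binned value
summarises the cell-body layer. Group-comparison tables delegate to
scipy (Welch t, Mann-Whitney) and statsmodels (two-way ANOVA) — standard
routines, not re-implemented.

## Problem sizes

Default synthetic datasets hold ~1,600 tiles and ~23,000 objects across
both genotypes, matching the scale of the source dataset (~10.5k CTL /
~13.2k cKO objects). The full 10,000-repetition bootstrap on both
metrics over all six groups runs in ~1.5 min on one CPU; calibration
suites use 500–1,000 repetitions and 10–50 seeds.
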