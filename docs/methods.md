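# Methods

This note records the model behind `radialpolarity`, the parameters that
matter, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## The measurement model

An acinus is treated as a roughly convex blob whose polarity state is
encoded in the radial distribution of a marker: apical markers concentrate
toward the lumen (center, for small-lumen acini), basal markers toward the
basement membrane (periphery), and loss of polarity flattens the
distribution. The pipeline reduces each acinus to

* a normalized radial profile RP₁..RPₙ, where RPᵢ is the mean marker
  intensity of concentric terrace *i* divided by the whole-ROI mean — so
  the area-weighted mean of the profile is identically 1 and the profile
  is invariant to multiplicative staining/exposure changes;
* the signed index RP = sign × Σᵢ |1 − RPᵢ|, a mean-absolute-deviation
  style dispersion about the flat profile. The sign is the negated sign of
  the ordinary least-squares slope of RPᵢ against the terrace mid-radius
  rᵢ = (i − 0.5)/n: descending ⇒ +1 (apical), ascending ⇒ −1 (basal),
  |slope| ≤ 1e-9 ⇒ 0.

The index separates polarized from uniform distributions and apical from
basal ones; it is deliberately insensitive to *where* along the radius the
signal peaks, so multimodal distributions are out of scope (the profile
vector itself is retained in the output for such analyses).

## Segmentation conventions

* 3×3 mean smoothing with reflected borders precedes thresholding.
* Otsu threshold over a 256-bin histogram of the (float) image; foreground
  is strictly above the threshold. A constant image yields an empty mask
  plus a warning.
* Border smoothing is morphological opening then closing with a disk,
  default radius 2 px — enough to remove single-pixel spurs that would
  otherwise seed the watershed.
* Hole filling (default on, `fill_holes`): the nuclear stain of an acinus
  is a ring of nuclei around the lumen, so its thresholded footprint can
  be annular; the ROI must be solid for the distance-map "mountain" to
  run center-to-periphery.
* Watershed on the negated Euclidean distance transform, seeds = regional
  maxima after h-maxima suppression of depth 2 px (default,
  `seed_suppression_depth`; raw regional maxima over-segment noisy
  blobs). Divide-line pixels are set to background. 8-connectivity
  throughout; coordinates are 0-based (row, col); bounding boxes are
  half-open.
* Label dilation, default 3 px at 20× (`dilation_radius`, set per
  magnification): grows each ROI into background only. Contested pixels
  go to the nearest original ROI, exact ties to the lower label id, so
  labels never merge and the result is independent of processing order.
* Filters run on the dilated ROIs, in fixed order border → size → blur,
  recording the first failing rule. The size range thus refers to final
  (dilated) ROI area. WAVR is computed only for ROIs surviving the first
  two rules.

## Focus measure

WAVR is computed on the un-masked bounding-box crop of the nuclear
channel (padded to ≥16×16), rescaled to [0, 1] — masking to the ROI would
inject artificial sharp edges, and the rescaling makes the measure
invariant to intensity scaling and offset. The crop undergoes a
single-level 2-D Daubechies-6 DWT; each subband is reconstructed to image
space and WAVR = (Σ|H|² + Σ|V|² + Σ|D|²)/Σ|A|². Defocus removes detail
energy, so WAVR decreases monotonically with blur; a constant crop scores
0 with a warning.

The absolute WAVR scale depends on the optics, camera and crop
statistics, so a fixed cutoff (config default 0.8, a value calibrated on
nuclear-stain epifluorescence images at 20×) will generally need
recalibration for other setups; exclusion is `wavr < cutoff`. Two
data-driven routes are provided:

* supervised: fit amplitude-scaled normals (Levenberg–Marquardt via
  `scipy.optimize.curve_fit`, initialized from histogram moments,
  Freedman–Diaconis binning) to the WAVR histograms of visually rated
  sharp and blurry classes, and take the equal-density intersection
  between the class means (closed-form root of the quadratic in log
  densities; midpoint fallback when no root lies between the means);
* unsupervised (`wavr_cutoff: auto`): a seeded two-component 1-D Gaussian
  mixture on the pooled WAVR values of the dataset feeds the same
  intersection rule.

## Terracing

For each ROI pixel, d = Euclidean distance to the nearest non-ROI pixel
(boundary pixels adjacent to background have d = 1). With peak distance
d_max, the height bin is ceil(n·d/d_max) clamped to 1..n and the terrace
index is n − bin + 1, so pixels at exactly d_max land in terrace 1 (the
center). n defaults to 8, within the 5–10 range that gives ~2-px-wide
bins for typical 20–40 px acinus diameters; it should scale with
magnification. ROIs with d_max ≤ 1 (1-px-thin shapes) or any empty
terrace are excluded as degenerate rather than re-binned: merging bins
silently would break cross-acinus comparability of RPᵢ.

The radial profile and its normalizer are both computed over the dilated
ROI, since the dilation exists precisely because the marker signal (true
membrane edge) lies outside the nuclear footprint.

## Group statistics

Per-group mean/SD/SEM of the RP index plus the group-mean profile;
pairwise comparison by the classical pooled-variance two-sample Student's
t-test, two-sided, df = n₁ + n₂ − 2 (Welch's form available behind a
flag). Degenerate inputs are defined: identical constant samples give
t = 0, p = 1; zero pooled variance with different means gives p = 0.
Acini are treated as independent units; `field_id` is recorded in every
output row so users can aggregate at the field or well level instead.

## Synthetic-data generator

`simulate_field` renders what the pipeline expects to see, at the
conditions used throughout the tests:

* 384×384 px fields (256×256 in the larger batch experiments), 8 acini
  (5 in the smaller fields) of radius 15–28 px placed by rejection
  sampling with ≥2 px clearance; an optional touching-pair mode places
  overlapping pairs to exercise the watershed.
* Nuclear channel: a contiguous chromatin band at 0.7 R around each
  center (cells abut around a small lumen) carrying 12 hard-edged
  nuclei disks of radius 2.5 px and multiplicative chromatin speckle
  (35%, 1-px correlation), all under a 0.8-px Gaussian optical PSF. The
  footprint deliberately under-covers the true extent, exercising the
  ROI-dilation rationale. Hard edges and speckle matter: they are the
  genuine high-frequency content whose destruction by defocus the WAVR
  measure detects.
* Polarity channel: linear radial laws in normalized radius ρ = r/R —
  1 + a(1 − ρ) apical, 1 + aρ basal, 1 nonpolar — with gradient strength
  a (default 1). The boundary value extends 2 px beyond R
  (`membrane_px`): markers occupy a membrane shell of finite thickness,
  so the dilated ROI does not fall off a hard signal edge. Small-lumen
  acini are assumed, so the apical law peaks at the center; an annular
  peak (large-lumen cysts) is not the default.
* Intensities on a 16-bit-like count scale: background 200, signal
  dynamic range 10,000, additive Gaussian noise of 50 counts (0.5% of
  range — a cooled-sCMOS read-noise floor). A configurable fraction of
  acini is defocused by Gaussian convolution (σ = 3 px in the QC
  experiments) applied to both channels before noise.
* Output is ordinary pipeline input (16-bit rasters, same readers and
  configuration), plus a ground-truth table (center, radius, phenotype,
  defocused, border flag) for evaluation.

What it does **not** emulate: signal-dependent shot noise (noise is
purely additive, so very dim acquisitions are out of its envelope),
realistic PSFs, 3-D geometry and projection artifacts, irregular acinus
shapes, multicellular texture in the polarity channel, debris and
illumination gradients. Tests passing on simulated fields therefore
demonstrate the algorithmic contracts (segmentation counts, profile
normalization, sign conventions, cutoff selection, calibration of the
t-test), not robustness to every real-world aberration; the WAVR scale
in particular is data-dependent and only orderings and classification
behavior transfer.

## Problem sizes used in the checks

The batch experiments run at 50 acini per group (5 per 256×256 field);
the type-I-error calibration simulates a population of 1,200 nonpolar
acini once through the full pipeline and then draws 1,000 disjoint
50-vs-50 replicates from it — under the null the draws are exchangeable,
so the t-test rejection rate estimates the type-I error without
re-rendering images per replicate.

## Known limitations

* The RP index is insensitive to radial shifts that preserve monotone
  ordering, and unsuited to markers with multimodal radial
  distributions; use the stored profile vectors for those.
* Under-segmentation of tightly packed acini can survive the watershed
  (about 2–3% of simulated fields show one extra or merged detection);
  seed-suppression depth and border smoothing trade over- against
  under-segmentation.
* The default WAVR cutoff is not portable across imaging systems; prefer
  the fitted or automatic cutoff on new data.
* Acini are assumed to be the independent statistical unit; field- or
  well-level clustering is left to the user.
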