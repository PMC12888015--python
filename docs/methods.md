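# Methods

## Problem setting

A TMA section is measured by MALDI-MSI on a 20 × 20 μm raster over
m/z 700–3000, then H&E-stained and scanned at sub-micrometer resolution.
Annotating the MSI data means deciding, per 20 μm spot, which tissue
compartment and diagnosis it belongs to. Manual subcore annotations are
coarse relative to follicular microanatomy: thyroid follicles are
epithelial rims (cell-rich, hematoxylin-dominant, finely textured)
around colloid lumens (smooth, eosin-pale). Colloid suppresses tryptic
peptide signal and carries matrix-adduct interferents, so spectra pooled
over coarse regions are diluted and contaminated. The package automates
cell-rich ROI selection from the H&E and quantifies what that buys
spectrally.

## Pixel classification

**Features.** 16 per-pixel features: {Red, Green, Blue, Hematoxylin} ×
{Gaussian, weighted deviation} × σ ∈ {2, 4} px at the 0.44 μm/px working
resolution. σ is interpreted in pixels; the Gaussian feature is a plain
blur, and *weighted deviation* is pinned as the Gaussian-weighted local
standard deviation sqrt(max(0, Gσ(I²) − Gσ(I)²)) with reflective
boundaries — non-negative, offset-invariant, zero on constant regions.
The hematoxylin channel is Ruifrok–Johnston color deconvolution with the
standard H&E optical-density vectors (rows unit-normalized, overridable);
automatic stain estimation is deliberately out of scope.

**Model.** A single linear layer with softmax: 16 × 2 = 32 parameters,
bias disabled by default so the parameter count is exactly the size of
the weight matrix. Features are z-scored with training-pixel statistics
stored in the model (raw OD and 8-bit intensity scales differ by orders
of magnitude). Training is full-batch gradient descent from a zero
initialization (the loss is convex), with a seeded subsample of at most
20 000 pixels per class; this makes retraining bit-reproducible for a
fixed seed. A hidden-layer variant was considered and rejected: it adds
nothing on linearly separable texture features and breaks the
32-parameter reading.

**Post-processing.** Binarize at 0.5 (argmax); remove 8-connected
objects with area < 7 μm² (37 px at 0.44 μm/px); fill 4-connected holes
with area < 7 μm²; vectorize components to polygons with surviving holes
preserved. The 8-connected-object / 4-connected-hole pairing is the
standard consistent raster topology.

## ROI construction

- **FC** — all spots present in the imzML whose centers fall inside the
  dearrayed core circle; "full core" is defined by the measured
  footprint, not the geometric circle alone.
- **PAT** — spots whose centers fall inside the pathologist polygons.
- **PC** — labeled detections buffered outward by 4 μm, then rasterized
  to the grid; spots outside the measured footprint or the core are
  dropped.

Spot membership is center-in-polygon everywhere: it is what MSI software
does when importing regions, it is order-independent, and it makes the
tiling testable against brute-force grid-center enumeration. The 4 μm
buffer (one fifth of the pitch) recovers rim spots that a strict
intersection would lose to the resolution gap; it is exposed as
`--buffer-um`. Label conflicts (a spot claimed by two labels, or an
exact-area tie in label transfer) resolve to the lexicographically
smallest label, deterministically. Labels are transferred by splitting
detections along annotation boundaries, so a detection straddling two
annotations contributes correctly-labeled pieces rather than a
majority-vote whole.

Dearraying thresholds mean optical density (default 0.04, catching pale
colloid), keeps large components, and clusters centers in x and y by
largest-gap splitting; row-major labels ("A1" …) with config-file center
overrides replacing interactive grid editing.

## Registration

`fit_affine` is a least-squares affine from ≥ 3 non-collinear control
points (image px → MSI μm), reporting the RMS residual in μm.
`refine_by_ion_image` then grid-searches translations (default ±60 μm in
5 μm steps, optional ±1° rotations) maximizing the Pearson correlation
between the reference-ion image (per-spot maximum within ±20 ppm of
m/z 1459.688 by default) and the tissue mask averaged over one spot
footprint and sampled at the mapped spot centers. An exhaustive search
is used instead of a gradient method because the residual misalignment
after manual coarse registration is small and determinism matters more
than speed at this problem size. A zero-variance ion image returns the
input transform with score NaN and a warning. The collagen identity of
the default reference ion is metadata; any m/z can be passed.

## Spectral processing

**Normalization.** Each spectrum is divided by its own RMS; all-zero
spectra are left untouched with a warning, and double normalization is
refused via a dataset flag.

**Peak picking.** Baseline = linear interpolation of per-window (50 Da)
percentiles; the default percentile is 50 (the windowed median). The
median is unbiased with respect to the noise floor — a lower percentile
sits ~1σ below it and silently inflates every S/N estimate — and is
robust here because peaks occupy a small fraction of any 50 Da window;
for peak-dense spectra the percentile is configurable. Noise = 1.4826 ×
median absolute deviation of the baseline-subtracted residual per 50 Da
window, interpolated. Peaks are local maxima of the residual with
(I − B)/noise ≥ 6 and (I − B) ≥ 0.3 % of the base-peak height
(thresholds applied after baseline subtraction), apex m/z refined by a
three-point parabola. On the documented benchmark (200 spectra, six
peaks each at S/N 10–30 plus a sub-threshold S/N-3 peak in every fourth
spectrum) the picker reaches sensitivity 1.0 at FDR 0 and never reports
the S/N-3 plants.

**Feature intensity.** Per-spot intensity of a peak-list feature is the
maximum of the baseline-subtracted signal within ±20 ppm of the feature
m/z — the ion-image convention. When the ppm window is narrower than the
axis spacing (±20 ppm at m/z 839 is ±0.017 Da against the fixture's
0.05 Da grid), the nearest axis sample is used; without this discrete-
axis guard such features would silently read zero.

**Matching.** Peak lists are matched one-to-one greedily by ppm distance
within ±20 ppm; partition sizes are conserved by construction.

## Discrimination

The interferent panel ships the ten printed HCCA-adduct m/z values
(839.08 … 1066.08) and the three trypsin autolysis peaks (842.51,
1045.56, 1220.64); the HCCA list is extensible through configuration
rather than padded with an invented value. Scores are per-m/z means over
spots, scaled per m/z so the maximum across ROI types is 1, plus percent
change of PC against each other type. PCA uses unit-variance column
scaling, 5 components, full SVD, with each component's sign fixed so its
largest-magnitude loading is positive. AUC uses the tie-corrected
rank-sum formulation (verified against brute-force pair counting to
1e-12); spots are treated as independent observations, a deliberate and
documented simplification — no per-patient pooling and no
multiple-testing correction is applied to the AUC flags.

## Synthetic fixture

The default phantom is a 2 × 2 TMA (one core per diagnosis: PTC, FVPTC,
NIFTP, FA), cores of radius 150 μm at 0.44 μm/px, MSI pitch 20 μm.
Each core carries one central macrofollicle (lumen 45 μm — large enough
to contain fully-colloid spots) and a ring of seven regular follicles
(lumens 16–22 μm, rims 9–13 μm); all cores share one layout, rotated
per core, so colloid load is not confounded with diagnosis. Rims render
hematoxylin-dominant with strong pixel-scale texture, lumens smooth and
eosin-pale. Pathologist-style polygons are built by morphologically
closing the union of follicle outer circles so they engulf the lumens,
reproducing the coarseness of real subcore annotations.

Spectra live on a uniform 0.05 Da axis; the default fixture uses
m/z 700–1600, which covers every planted signal (interferent panel
839–1220, class markers ≤ 1522, reference ion 1459.688) at a tractable
cube size — the generator accepts the full 700–3000 range. Peaks are
Gaussian with σ = 0.08 Da on a flat baseline (3 a.u.) with white noise
(σ = 1 a.u.); amplitudes are kept a modest multiple of the baseline so
peaks contribute little to a spectrum's total RMS, as in real
profile-mode data — otherwise RMS normalization itself would cancel the
colloid-enrichment contrast the fixture is supposed to exhibit.
Per-diagnosis marker peptides and shared peptides scale with the
cell-rich area fraction of each spot footprint, the reference ion with
the tissue fraction, interferents with (1 + 4 × colloid fraction), and
trypsin peaks are uniform. The planted image→MSI affine is emitted as
ground truth.

What the fixture does **not** emulate: realistic histology texture and
stain variation, isotope envelopes, mass-resolution-dependent peak
widths, ion mobility, chemical baselines, patient-level heterogeneity
(one core per diagnosis) and inter-core intensity drift. Passing tests
therefore demonstrate correctness of the algorithms under the planted
generative model, and directional recovery of the expected biology
(interferent suppression and peptide S/N gain in cell-rich ROIs); they
are not a claim about effect sizes on real tissue.

## Numerical choices and degenerate inputs

- Fractions of a spot footprint use the actual number of image pixels
  binned into that grid cell (the pixel grid does not divide 20 μm
  evenly, so the nominal count would make fractions overshoot 1).
- Empty phantom → blank image with empty annotation sets; no tissue
  under the grid → an error naming the registration/footprint mismatch.
- Zero-variance PCA columns are dropped with a warning; inseparable
  training classes warn and report chance-level accuracy; a flat
  spectrum yields an empty peak list.
- imzML is written in continuous mode as float64, so read(write(ds)) is
  bit-exact; processed-mode files are resampled onto the union axis by
  linear interpolation and flagged.
- All randomness flows through explicit seeds; identical seeds give
  bit-identical rasters, cubes and trained weights.

## Problem sizes

Default test and acceptance runs use the 2 × 2 fixture above
(~1730 px square image, ~690 MSI spots, 18 001-point spectra), 200
benchmark spectra for the peak picker, 1000 random samples for the AUC
oracle and 100/50 cases for the geometry oracles. These sizes were
chosen as the smallest at which every planted structure (pure-colloid
spots, per-class markers, sub-pitch registration) is still represented.
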