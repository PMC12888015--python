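# morphomsi

Morphology-guided annotation of MALDI mass spectrometry imaging (MSI)
data, for spatial-proteomics groups working with tissue-microarray (TMA)
material — demonstrated here on thyroid-nodule histology.

MALDI-MSI acquires a full mass spectrum on every 20 × 20 μm spot of a
tissue section, but the regions a pathologist outlines on the matching
H&E stain are coarse: in thyroid tissue they unavoidably include
colloid-filled follicle lumens, which suppress tryptic-peptide signal and
promote matrix (HCCA) cluster adducts. `morphomsi` replaces coarse
outlines with automatically detected **cell-rich** regions:

1. **Pixel classification** — the H&E raster (0.44 μm/px) is expanded
   into 16 multiscale features (Gaussian and Gaussian-weighted local
   standard deviation, σ ∈ {2, 4} px, on the R/G/B channels and the
   hematoxylin optical density from Ruifrok–Johnston color
   deconvolution). A 32-parameter linear-softmax classifier (16 features
   × 2 classes, no bias), trained on ~15 small annotations per class,
   labels every pixel cell-rich vs non-cell-rich. The probability map is
   binarized at 0.5; objects and holes smaller than 7 μm² are removed.
2. **Label transfer and tiling** — detections inherit diagnosis labels
   (PTC / FVPTC / NIFTP / FA) from the pathologist annotations by
   maximal-overlap assignment with splitting along annotation
   boundaries, then are buffered by 4 μm and rasterized onto the MSI
   grid (center-in-polygon spot membership).
3. **Registration** — an affine image→MSI transform from control points,
   refined by maximizing the Pearson correlation between the tissue mask
   and the ion image of a reference peptide (default m/z 1459.688, a
   collagen-derived tryptic peptide present across tissue).
4. **Spectral comparison** — three ROI types per core: **FC** (full
   core: all measured spots in the core), **PAT** (pathologist
   polygons) and **PC** (pixel-classifier detections). Spectra are
   RMS-normalized; per-ROI mean spectra are peak-picked at S/N ≥ 6 with
   a 0.3 % relative-intensity floor; per-spot feature intensities feed
   an interferent-panel score, unit-variance PCA (5 components) and
   per-feature ROC analysis, where a feature is *discriminatory* for a
   class pair when its rank-sum AUC is > 0.7 or < 0.3.

Because public TMA + MSI pairs are large and partly proprietary, the
package ships a first-class synthetic fixture generator
(`morphomsi.fixtures`): paired H&E-like cores with follicular
ground-truth masks and an imzML cube in which peptide peaks scale with
the cell-rich fraction of each spot, HCCA adducts with the colloid
fraction, and trypsin autolysis peaks are uniform. Every stage of the
pipeline is tested against this planted ground truth.

## Worked example

Run the whole pipeline on the default synthetic fixture:

```bash
morphomsi run --seed 1 --out results/demo
```

which prints

```json
{
  "spot_counts": { "FC": 688, "PAT": 399, "PC": 271 },
  "discriminatory_counts": { "FC": 4, "PAT": 4, "PC": 4 }
}
```

and writes the full report to `results/demo/summary.json`. Reading the
numbers: of the 688 measured spots per fixture (FC), the pathologist-style
outlines keep 399 (PAT) and the pixel-classifier ROIs keep 271 (PC) —
the cell-rich subset. In `summary.json` the HCCA-adduct panel intensity
in PC is 7.0 % lower than FC and 21.5 % lower than PAT (the colloid-rich
spots were excluded), while the S/N of the shared tryptic peptides in
the PC mean spectrum is ~1.4× that of FC. All four planted
class-specific peptide markers are flagged as discriminatory (AUC > 0.7)
in the PC ROIs.

Individual stages are available as subcommands (`morphomsi simulate`,
`train-pc`, `predict`, `dearray`, `register`, `transfer-labels`, `tile`,
`mean-spectrum`, `peakpick`) and as library functions; see the module
docstrings under `src/morphomsi/`.

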