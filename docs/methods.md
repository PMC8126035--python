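# Methods

## The counting protocol

`hemocount` detects Group II granular hemocytes in 8-bit RGB HE micrographs
by treating detection as a one-class color/texture segmentation followed by
shape-based exclusion. The assumptions are those of routine HE histology:
stable staining and illumination across a slide series (capture settings
fixed on the controls), eosin-pink tissue, near-white empty regions, and a
hemocyte class whose granular cytoplasm gives it a color/texture signature
that ordinary tissue lacks.

### Background model

A pixel is classified as empty slide iff `green ≥ τ_G` **and** `blue ≥ τ_B`
(defaults `τ_G = τ_B = 200` of 255). Eosin is the dominant red stain, so
tissue is recognized by its suppressed green; requiring both channels
protects weakly-blue hematoxylin regions from being discarded. Background
pixels stay in the raster (neighborhood windows remain defined everywhere)
but are excluded from model fitting, projection rows and object masks.
The thresholds are one global config; the protocol presumes acquisition
settings were normalized across the image series.

### Pixel-neighborhood PCA

Each retained pixel is unfolded into the concatenation (channel-major,
window row-major) of the `(2r+1)²` neighborhood intensities of each
channel. `r = 2` (a 5×5 window, 75 features) by default: large enough that
a window straddling granules and cell body encodes the granular texture,
small enough that the model stays local. Borders replicate the edge pixel,
which introduces no artificial color edges.

The PCA model is fitted on the unfolded *training image*: annotated
hemocyte rectangles cropped from ~10 micrographs, background-stripped, and
shelf-packed onto a white sentinel mosaic with at least `2r` px of padding
between tiles. Rows whose window overlaps **any** invalid pixel (sentinel
padding or in-tile background) are dropped so that white never leaks into
the hemocyte model — without this the low-quantile score threshold is set
by contaminated window-edge rows rather than by hemocyte appearance.

Fitting mean-centers the matrix (no variance scaling: all channels share
the 0–255 scale) and takes a full LAPACK SVD — deterministic, no randomized
solver. The model keeps `n_components = 10` loading vectors plus the full
eigenvalue spectrum (sample normalization, `n−1`), so the trace identity
`Σλ = total variance` holds and persisted models reload bit-exactly from
JSON (floats serialized via `repr`).

### Component selection, orientation, threshold

Eigenvector signs are arbitrary, and the component on which hemocyte
features concentrate depends on the microscope/staining configuration (the
reference configuration used PC4; the synthetic optics put the signature on
PC1). Two conventions make the single `score ≥ τ` rule well defined:

* every loading is first oriented so its largest-magnitude element is
  positive (the naive rule — "mean training score ≥ 0" — is vacuous,
  because centering makes every component's mean training score exactly 0);
* at calibration the package computes, per component, the standardized
  separation `(mean score of annotated hemocyte pixels − mean score of
  other tissue pixels) / pooled SD` on the training micrographs.
  `selected_pc="auto"` picks the component with the largest |separation|;
  an explicit index is kept but sign-flipped if needed so hemocytes are
  always the high-score side.

The score threshold τ is the `q`-quantile (default 0.05) of the training
hemocyte scores on the selected component: thresholding the training
image itself retains ~95 % of hemocyte pixels, while out-of-distribution
tissue (pink background, white lumina) projects far below. The quantile
rule is this package's design; choosing τ by visual inspection of the
score image is equally compatible with the model format.

### Objects and shape exclusion

The thresholded mask is closed with a radius-1 structuring element
(Chebyshev disk, i.e. a 3×3 square — granular staining fragments cell
interiors and the closing example semantics require gap-2 fragments to
merge) and hole-filled, then labeled with 8-connectivity. Per component:
area, bounding-box width/height, perimeter (scikit-image's weighted
contour-step estimator: axial steps 1, diagonal √2, corner configurations
(1+√2)/2), convex area, circularity `4πA/P²` and solidity `A/A_convex`.
Circularity is clipped at 1.15 before filtering because the perimeter
estimator overshoots on small rasterized disks; components with zero
estimated perimeter (single pixels) take the clipped maximum — such specks
are maximally compact and must be excluded by size, not by shape.

Filter bounds are calibrated from the training cells as the pipeline itself
detects them: observed min/max of area/width/height widened by ±50 %, and
circularity/solidity minima scaled by 0.5. Criteria are evaluated in the
fixed order area, width, height, circularity, solidity, and each rejected
object records its first failure. In practice small dark nuclei share the
hemocyte's high score but fail the area minimum; elongated fibers that
survive the score threshold fail circularity.

### Statistics

Counts (one observation per image, untransformed) are compared with
classical one-way fixed-effects ANOVA (`F = MSB/MSW`, p from the F
distribution) and the Tukey–Kramer test: for each pair,
`SE = √(MSW/2·(1/nᵢ+1/nⱼ))`, `q = |Δmean|/SE`, adjusted p from the
studentized-range distribution with `(k, N−k)` df. With balanced groups
the Kramer SE reduces to the classical Tukey HSD. Counts per field are
convertible to densities via the physical field area (0.048 mm² for the
default 256×256 px field at 0.8559 µm/px). Snail-level random effects are
out of scope; each image is treated as independent within its group.

## The synthetic generator

`SyntheticSpec` encodes what the detection task exploits, not slide optics:

| feature | default | rationale |
|---|---|---|
| field | 256×256 px @ 0.8559 µm/px | the 0.048 mm² field of a 40× objective |
| eosin background | RGB (236,182,193), smooth texture amplitude 5 | HE-stained connective tissue |
| lacunae | bright (250,248,250) blobs, 8 % of area | hemolymph spaces removed by the background threshold |
| hemocytes | Poisson λ (study-dependent), radius 7–10 px, purple body (158,100,168), granules (96,52,120) at density 0.45 with ±12 jitter | 12–17 µm Group II granular hemocytes; granule speckle is the discriminative texture |
| placement | inside a bright halo (body + 6 px) | hemocytes reside in blood-containing lacunae |
| nuclei | 30/field, radius 2–3 px, dark blue (64,62,138), smooth | share the hue, lack size and texture — excluded by shape/size |
| fibers | 5/field, 3–5 px wide, 40–80 px long, pink-red (196,100,122) | share smoothness, fail circularity |
| optics | Gaussian blur σ 0.6, pixel noise σ 2 | mild sensor/optics model |

Objects are mutually disjoint: pairwise center distance must exceed
`max(min_separation, rᵢ+rⱼ+4)`; fibers are placed as segments that may
cross each other but keep clear of every lacuna. Four independent random
streams (background, hemocytes, confounders, noise) are spawned from the
seed in documented order, so toggling confounders never moves a hemocyte
or changes the noise field, and everything is bitwise deterministic per
(spec, seed).

What the generator does **not** emulate: real stain variability and color
bleed, touching/overlapping cells, partial-volume effects of 7 µm sections,
out-of-focus planes, hemocytes embedded in dense tissue rather than
lacunae, and the agranular hemocyte classes. Passing the synthetic
benchmarks therefore shows the pipeline's machinery is correct and that the
protocol recovers planted abundance differences under its stated
assumptions — not that any particular sensitivity will transfer to real
slides, where threshold and filter calibration against real annotations is
the point of the calibration phase.

## Problem sizes and numerical choices

* Study benchmark: 30 fields per group (control λ=2, regenerating-like
  λ=14, a planted 7-fold difference), training on 10 fields of 5 cells —
  comparable to the reference design (60–111 images/group) at a size that
  runs in seconds per group.
* Orthonormality asserted to 1e-8; trace identity to 1e-6 relative; score
  refolding exact on valid pixels; quantiles via numpy's default linear
  interpolation (median of n scores leaves ⌈n/2⌉ at or above it).
* Degenerate inputs: all-identical observations raise a degenerate-variance
  error rather than returning F=∞; a training matrix with fewer rows than
  features warns (rank-deficient model); an annotation that is entirely
  background contributes nothing and logs a warning; requested object
  counts that cannot be placed at the separation constraint raise a
  placement error reporting the achieved count.
* Detection counts depend on the score threshold only through a wide
  margin: on synthetic fields the background sits >10 pooled SDs below the
  hemocyte score distribution, so the 5 % quantile choice is not delicate.

## Known limitations

* One component, one threshold: multi-component segmentation rules and
  wavelet texture features (needed for agranular classes) are out of scope.
* No watershed splitting: two hemocytes closer than the closing diameter
  merge into one object (the generator's separation constraint avoids this
  regime; real clustered infiltrates would be undercounted).
* Rectangle annotations only; no interactive tooling.
* The shape filter is calibrated from as few as ~10 training cells;
  its ±50 % margin is deliberately loose and should be reviewed when
  transferring to a new magnification.
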