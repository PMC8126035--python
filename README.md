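# hemocount

Marker-free, computer-assisted counting of **Group II granular hemocytes**
in hematoxylin–eosin (HE) stained brightfield micrographs.

Invertebrate immune cells (hemocytes) lack validated molecular markers in
many species, including the apple snail *Pomacea canaliculata*, so
tissue-resident hemocytes are usually counted cell by cell at the
microscope. Granular hemocytes, however, have a distinctive HE appearance —
a purple cell body densely speckled with stainable cytoplasmic granules —
that can be isolated from ordinary histology colors by multivariate image
analysis. `hemocount` implements that protocol end to end:

1. **Background removal** — a pixel is empty slide iff it is bright in both
   the green and the blue channel (`G ≥ τ_G ∧ B ≥ τ_B`); eosin-pink tissue
   has suppressed green and survives.
2. **Pixel-neighborhood unfolding (MIA)** — every tissue pixel becomes a
   feature row holding the RGB intensities of its whole `(2r+1)×(2r+1)`
   neighborhood: `p = 3(2r+1)²` features (75 for the default `r = 2`).
3. **PCA score images** — a PCA model is fitted once on the unfolded
   *training image*, a mosaic assembled from manually annotated hemocytes.
   Projecting any image on one principal component and refolding the score
   vector `t = (x − x̄)ᵀ v` to image geometry yields a score image in which
   hemocyte pixels score high.
4. **Score thresholding** — pixels with `t ≥ τ` (τ = a low quantile of the
   training hemocyte scores) are hemocyte candidates.
5. **Object identification and shape exclusion** — the candidate mask is
   consolidated (closing + hole filling), labeled, and each connected
   component is measured: area, width, height, circularity `4πA/P²` and
   solidity `A/A_convex`. Objects outside the calibrated hemocyte envelope
   (small smooth nuclei, elongated muscle fibers) are excluded; the
   survivors are the counted hemocytes.
6. **Statistics** — per-image counts are compared across experimental
   groups with one-way ANOVA and the Tukey–Kramer studentized-range test
   (`SE_ij = √(MSW/2 · (1/nᵢ + 1/nⱼ))`).

Because no real micrograph data are distributed, the package ships a
first-class synthetic generator (`hemocount.synthetic`) producing HE-like
fields — eosin background, bright hemolymph lacunae, granular hemocytes,
nucleus and fiber confounders — with exact ground truth, so every stage is
testable and the whole pipeline can be benchmarked against planted counts.

The trained protocol is exposed as a scikit-learn-style estimator:

```python
from hemocount import HemocyteCounter, SyntheticSpec, generate_training_set, generate_field

spec = SyntheticSpec()
images, annotations, _ = generate_training_set(spec, n_images=10, seed=1)
counter = HemocyteCounter(selected_pc="auto").fit(images, annotations)

img, truth = generate_field(spec.replace(hemocyte_count=5), seed=7)
print(counter.detect(img).count)   # -> 5
```

## Worked example (CLI)

Simulate a two-group study (control with Poisson mean 2 hemocytes per
0.048 mm² field vs a regenerating-like group with mean 14), calibrate, count
and compare:

```
$ hemocount simulate --out study --seed 17 --control-lambda 2 --regen-lambda 14 --n-per-group 30
study written to study (60 images)

$ hemocount train --images train_images --annotations annotations.json \
      --config config.json --out model.json
INFO trained on 50 tiles; leading eigenvalues 1735.7, 1608.5, 1570.7, 1276.8, 1178.9; selected PC1, threshold -68.832
model written to model.json

$ hemocount count --model model.json --images study/images \
      --groups study/groups.csv --config config.json --out counts.csv
counts written to counts.csv

$ hemocount stats --counts counts.csv --out stats.json
ANOVA: F(1, 58) = 343.202, p = 4.93e-26
  control vs regen: diff = -12.233, p_adj = 0 *
```

Here `config.json` is `{"selected_pc": "auto", "pixel_size_um": 0.8559}`:
the segmentation component is configuration-specific, and `"auto"` lets the
built-in separability diagnostic pick it (PC1 for the synthetic optics; the
reference microscope configuration used PC4). The counts table gives
detected group means 2.10 ± 1.35 (control) and 14.33 ± 3.36 (regenerating),
a 6.8-fold difference recovered from a planted 7-fold difference, with the
pair flagged significant by Tukey–Kramer at α = 0.05.

The training inputs (`train_images/`, `annotations.json`) come from
`generate_training_set`, which plants clear hemocytes and emits their
bounding rectangles as annotations — the stand-in for the one-off manual
singling-out an operator performs during calibration. On real data the
annotations are a JSON list of rectangles
(`[{"image": "...", "rect": [row0, col0, n_rows, n_cols]}]`) drawn in any
image tool.

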