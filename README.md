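# gliaquant

Quantitative histology of amyloid plaques and microglia on calibrated
fluorescence images, with a synthetic-data benchmark that carries exact
ground truth.

The package is built for studies of astrocyte-derived APOE in amyloid-mouse
cortex, where the readouts are: how many fibrillar (X-34⁺) plaques form and
how compact they are; how microglia (Iba1⁺) redistribute around plaques;
how many soluble Aβ aggregates a brain extract yields in single-molecule
pulldown (SiMPull/TIRF) frames; and how guanidine-soluble Aβ42 responds to
APOE dose per isoform. Because the original measurements come from animal
tissue, the package ships a generator that emulates those data with known
truth, so every stage of the quantification is testable end to end.

## What it computes

- **Plaque morphometry.** Semantic masks (trainable random-forest pixel
  classifier over a multi-scale filter bank, or Otsu thresholding) are
  instance-segmented (8-connected, ≥ ~4 µm equivalent diameter) and each
  plaque gets size, location, a size class (< 20 / 20–40 / > 40 µm), and a
  compactness score: the Angular Second Moment of the gray-level
  co-occurrence matrix computed strictly inside the instance,
  ASM = mean_θ Σ_ij p_θ(i,j)², with intensities min–max quantized to 64
  levels and pairs at distance 1 in four directions. High ASM = homogeneous
  dense core; speckled diffuse halos score low.
- **Microglia instancing.** Touching cells are separated by a weighted
  fusion of two exact Euclidean distance transforms — EDT of the full
  semantic mask plus a higher-weighted EDT of the soma mask — followed by a
  seeded watershed from the soma centroids (fused = w_proc·EDT(mask) +
  w_soma·EDT(somata), w_soma > w_proc).
- **Per-cell spatial morphometrics.** Convex-hull territory (µm²), total
  process length (skeleton of instance minus body; diagonal steps √2 px),
  mean distance to the 3 nearest neighbours, and the plaque-association
  rule: a cell is plaque-associated iff its centroid is inside the
  thresholded plaque area or within 5 µm of a plaque edge.
- **Spot counting.** DoG band-pass, threshold at median + k·MAD (k = 5),
  area-filtered components with local-maxima splitting, aggregated as mean
  of means: 9 frames → technical replicate → mouse.
- **Statistics.** Dose–response OLS (Aβ42 ~ APOE per group),
  confounder-adjusted multiple regression (treatment contrast given APOE
  level), one-way ANOVA + Tukey, unpaired t, random-intercept linear and
  binomial mixed models (mouse as grouping factor), hypergeometric/Fisher
  enrichment, and an exact multi-set intersection test: the distribution of
  |S₁ ∩ … ∩ S_m| for independent uniform fixed-size subsets of an N-element
  background, computed by iterated hypergeometric convolution (stable at
  N ≈ 25,000).

## Worked example

```python
import gliaquant as gq

spec = [g for g in gq.default_groups() if g.name == "APOE4"][0]
fov, gt = gq.generate_fov(spec, seed=7)          # 438.88 µm field, 0.43 µm/px

mask = gq.threshold_plaques(fov.channel("plaque"), noise_floor_sigmas=6.0)
labels, recs = gq.segment_plaques(mask.mask, fov.pixel_size_um)
gq.compute_plaque_asm(fov.channel("plaque"), labels, recs)
summ = gq.summarize_fov(recs, fov)
print(summ.n_plaques, round(summ.area_fraction, 4), gt.n_plaques)
```

prints

```
29 0.0422 29
```

— 29 plaques segmented (matching the 29 rendered), covering 4.2% of the
field. Each record carries its ASM; on the compactness sweep
(`analysis/02_plaque_morphometry.py`) the median ASM rises from 0.0008 for
diffuse plaques (core fraction 0.2) to 0.034 for dense ones (0.9), the
monotone readout the texture feature exists for.

The numbered scripts under `analysis/` run the full study narrative on the
default synthetic cohort and write their tables to `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_plaque_morphometry.py --seed 0
python analysis/03_microglia_segmentation.py --seed 0
python analysis/04_spot_counts.py --seed 0
python analysis/05_regression_stats.py --seed 0
```

`05` reports, among others, the pooled regressions of microglia counts on
plaque area fraction — plaque-associated counts rise steeply
(slope ≈ 1000 cells per unit area fraction, R² ≈ 0.98) while
non-plaque-associated counts stay flat-to-declining — and the
depletion-arm treatment contrasts on Aβ42 adjusted for APOE level.

There is also a CLI for running stages on image files
(`gliaquant simulate|classify|plaques|microglia|spatial|spots|run-all`);
`gliaquant run-all --config run.yaml --seed 1` executes the whole pipeline
reproducibly and writes per-stage CSVs plus a machine-readable
`summary.json`.

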