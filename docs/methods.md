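# Methods

This note documents the models, conventions and numerical choices behind
gliaquant, and what the synthetic benchmark does and does not establish
about real tissue data.

## The synthetic study

The generator emulates a four-group design — an APOE-knockout group plus
three groups expressing human APOE2/3/4 from astrocytes in an amyloid mouse
— at the level the downstream quantification consumes: calibrated 2D
fluorescence fields, TIRF spot frames, and per-mouse measurement tables.

**Calibration.** The default rendered field is 438.88 µm square (the 40×
objective's field) sampled at 0.43 µm/px (1021 px); the 20× field
(880.42 µm) is available as a constant. Pixel size is a free parameter
because frame pixel dimensions are not fixed by the physical field size
alone; the field-of-view container enforces `n_px · pixel_size ≈ fov_size`
within one pixel.

**Plaques.** Counts are Poisson per field (group means: APOE4 25, APOE2 12,
APOE3 6, knockout 0 — ordered as isoform plaque burdens observed in astrocytic-APOE amyloid models);
diameters are log-normal (median 20 µm, σ_log 0.35), spanning the study's
20–40 µm and > 40 µm analysis bins. Each plaque is a bright homogeneous
core disk of radius `core_fraction × r` inside a speckled halo whose pixels
draw uniform intensities — so after per-plaque min–max quantization the
core occupies few gray levels and the halo many, making the measured ASM a
monotone function of `core_fraction` (the generator's compactness knob;
default Beta(4, 4)). Plaque intensities are bright (core 3200 counts)
specifically so Poisson shot noise does not smear the core across
quantization levels; with dim rendering the ASM contrast drowns in noise.
Placement enforces ≥ 2 µm edge separation (200 rejection attempts, then
overlap is accepted), so plaque area fraction is Σπr²/A exactly and
component counts are exact on the rendered masks.

**Microglia.** A homogeneous background pool (Poisson, default 60 cells per
field) is placed uniformly; recruited cells (Poisson with mean
`pa_recruitment_coeff × area_fraction`, default coefficient 900) are placed
in the peri-plaque ring (plaque radius −2 µm to +4 µm). Ground-truth
association uses the same 5 µm edge rule as the measurement stage, applied
to the continuous disk geometry. Background cells that happen to fall
within 5 µm of a plaque are associated too, so the non-associated count
*declines* with plaque load rather than staying exactly flat — this is what
makes the fitted non-associated slope reliably non-positive, matching the
published sign structure of such regressions — associated counts rising
steeply (≈ +970 cells per unit area fraction) while non-associated counts
decline (≈ −240); the generator's defaults give ≈ +1000 and ≈ −120. Cells render as Gaussian-
blurred somata (radius 3.5 ± 0.4 µm) with 3–6 branch processes, each a
persistent 8-neighbour random walk of known summed step length (8–25 µm
targets), giving an exact truth for skeleton-length validation. Pixels
contested by overlapping cells belong to the nearer soma centre.

**Dose–response.** Per mouse, APOE level is log-normal (median 2000
arbitrary ELISA units, σ_log 0.4; identically zero in the knockout) and
Aβ42 = intercept + slope·APOE + N(0, σ). Slopes are the isoform-specific
values 0.23 / 0.11 / 0.005 (APOE4/2/3); per-group noise SDs (150/105/100)
were set once so the expected R² matches the published fits (≈ 0.6 for
APOE4, ≈ 0.4 for APOE2, ≈ 0 for APOE3). A mouse's plaque density scales
with its Aβ42 relative to the group expectation, coupling plaque load to
amyloid burden. Depletion arms multiply microglial densities by the
surviving fractions 0.17/0.23/0.13 (83/77/87% depletion, the published CSF1R-inhibition efficacy per group) and
shift the Aβ42 intercept by the published treatment contrasts.

**Spot frames.** K ~ Poisson(rate) Gaussian spots (σ 1.5 px) on a
background of 50 counts; SNR is peak amplitude over the background noise SD
(√(shot + read²)), default 10. Group rates (knockout 140, APOE2 80, APOE3
45, APOE4 40 per frame) follow the published ordering of soluble-aggregate
counts (knockout highest). Cohorts use 3 technical replicates × 9 frames
per mouse, 3 imaging fields per mouse, and 4–10 mice per group depending on
the analysis, mirroring the study's unit structure.

**Noise.** All channels get Poisson shot noise plus additive Gaussian read
noise (SD 2). Everything is drawn from `numpy.random.default_rng`, with
per-mouse/per-field child seeds derived by hashing stage names from one
global seed — so tables are bit-identical whether or not images are
rendered, and any stage can be rerun in isolation.

**What the benchmark does not emulate:** optical PSF beyond Gaussian blur,
photobleaching, uneven illumination, 3D structure (fields are 2D
projections), autofluorescence, vascular amyloid, and real microglial
morphology (branches are random walks, not Sholl-realistic arbors).
Passing tests therefore demonstrates correctness of the measurement
operators and statistics under controlled conditions, not segmentation
accuracy on real tissue.

## Measurement conventions

**Filter banks.** The plaque bank uses σ ∈ {1, 2, 4, 8} px and the
microglia bank σ ∈ {2, 4, 8, 16, 32, 64} px (dyadic scale sets); per σ:
Gaussian, DoG (σ paired with 1.6σ, the standard blob-detection ratio),
gradient magnitude, Laplacian of Gaussian, Hessian eigenvalues (λ1 ≥ λ2);
the microglia bank adds mean and max over a (2σ+1) square. The raw image is
included once as the identity plane (F = 25 and 49). Boundaries reflect.
The classifier is a 100-tree random forest with √F features per split and a
fixed seed.

**GLCM/ASM.** 64 quantization levels on the per-plaque min–max range
(illumination-invariant), distance-1 offsets at 0°/45°/90°/135°, symmetric
normalized matrices, pairs restricted to mask-interior pixels so halo
background cannot inflate homogeneity, per-angle ASM averaged (rotation
invariance at the feature level). Angles with no valid pair are excluded;
with no valid angle the ASM is NaN and flagged.

**Body/process split and fusion.** Body = mask pixels with EDT ≥ 3 µm;
processes are closed with a square structuring element of side 2r+1
(default r = 2 px) — a square, not a Euclidean disk, because a digital disk
cannot bridge a 1-px gap in a 1-px-wide process, which is precisely the
continuity error the closing exists to fix. Fusion weights default to
w_soma = 2, w_proc = 1 (the soma map must dominate; the exact ratio is
config-exposed). The watershed floods the negated fusion with 8-
connectivity; seeds outside the mask are dropped with a warning; mask
components unreached by any seed are attached to the nearest label so the
labels always partition the working mask.

**Recovery on overlapping cells.** On ~100-cell fields with branch
crossings, a cell's distal branch segment beyond a crossing is geodesically
closer to the neighbouring soma and is assigned there; per-field 1:1
recovery at IoU ≥ 0.5 therefore ranges 91–100% (mean ≈ 96%) across seeds.
The recovery contract is validated as pooled recovery over ten fixed
default fields (with a 90% per-field floor). In 3D stacks crossings are far
rarer; operating on 2D projections is this package's documented
simplification.

**Morphometrics.** Territory is the convex hull of pixel centres (a tiny
cell's hull can be smaller than its pixel area — the convention is
documented rather than "fixed"). Process length sums 8-connected skeleton
steps (1 px orthogonal, √2 diagonal, diagonals skipped when an orthogonal
intermediate exists); ±5% tolerance acknowledges skeletonization bias on
thick or branched shapes. The 3-NN clustering statistic needs ≥ 4 cells,
else NaN with a warning. Association uses the exact EDT of the plaque-mask
complement sampled at the centroid's pixel; signed distance is negative
inside plaques; border-touching cells are flagged so group comparisons can
exclude edge-truncated territories.

**Spot detection.** The brightness rule is median + k·MAD of the DoG frame
with σ-consistent MAD (×1.4826) and k = 5; components outside 2–50 px are
dropped; local maxima at ≥ 3 px separation split partially merged
neighbours; a 4σ border margin is excluded because boundary reflection
inflates the DoG at frame edges. A flat frame (MAD = 0) yields zero spots
via an epsilon floor. These concrete values stand in for unpublished
plugin thresholds; all are config-exposed and shared across frames by
construction.

## Statistics

OLS and multiple regression are ordinary least squares with two-sided
t-tests (they match the normal equations to 1e-10 in tests); a constant
response reports R² = 0. ANOVA pairs with Tukey's studentized-range
comparisons; the t-test offers Welch. The Gaussian mixed model is a
random-intercept LMM fitted by REML with Wald p-values; the binomial mixed
model is a random-intercept logistic fit by variational Bayes (posterior
mean and SD, normal-approximation p) — estimator choices made here, where only software names are conventionally stated. Residual quantiles are exported for Q-Q
normality checks. Bonferroni multiplicities must be supplied by the caller.

The multi-set intersection test computes the exact law of
|S₁ ∩ … ∩ S_m| for independent uniform fixed-size subsets: conditioning on
the running intersection of size s, its overlap with the next n_j-subset is
Hypergeom(N, s, n_j), so the pmf follows by iterated hypergeometric
convolution over the running support. This is the same distribution as the
inclusion–exclusion closed form but needs no signed large-term
cancellation, and is numerically exact at backgrounds of ~25,000 genes
(pmf sums to 1 within 1e-9; reduces to the hypergeometric at m = 2;
verified against exhaustive enumeration at small N and a 10⁵-draw
Monte-Carlo oracle at full scale).

## Pipeline and problem sizes

`run_all` fans one global seed out to per-stage child seeds (SHA-256 of
"seed/stage", reduced below 2³¹), writes per-stage CSVs, a sorted-key
summary JSON (bit-identical across reruns of the same config), and a run
log echoing the configuration. In the orchestrated image path the
association mask is the *segmented* (≥ 4 µm) plaque area and an Otsu
foreground must clear a 6-MAD robust noise floor — otherwise a plaque-free
noise channel would threshold at its upper noise tail.

Default analysis sizes — 6–10 mice per group, 3 fields per mouse, 27 TIRF
frames per mouse, 100-replicate pattern checks at the table level, and
full-resolution rendering only where an image measurement is under test —
were chosen to keep the whole suite desk-scale while leaving every
statistical conclusion comfortably powered.

## Known limitations

- 2D only; no 3D watershed or hulls.
- The soma detector is a classical blob detector (smooth/threshold/area
  filter) with an external-centroid escape hatch; it is not a learned cell
  detector and will merge deeply overlapping somata.
- ASM is the only Haralick feature computed.
- The binomial mixed model's variational posterior can shrink variance
  components; its parameter-recovery contract (15% on a unit log-odds
  effect) is the tested guarantee.
- Generator realism limits listed above; in particular branch random walks
  cross more often than real arbors, making the pooled recovery figure a
  conservative bound.
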