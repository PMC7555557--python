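# Methods

## Coordinate and image conventions

All grids are 0-based `(row, col)`; pixel `(r, c)` covers the half-open
square `[r, r+1) × [c, c+1)` with center `(r+0.5, c+0.5)`. Rows are axial
depth and columns lateral width, matching the screen orientation of a
clinical sonogram; the depth-to-width ratio (DWR) relies on this
assignment and maps to its reciprocal under a 90° rotation. ROI polygons
are rasterized by the even-odd rule on pixel centers. When a grayscale
view of an RGB Doppler frame is needed, ITU-R 601 luma is used.

## Grayscale features

Geometry rests on two primitives:

- an **equivalent ellipse**: centroid plus axis directions/ratio from the
  mask's second central moments, rescaled so the ellipse area equals the
  mask area. Its perimeter (Ramanujan's second approximation, relative
  error < 1e-4 at the eccentricities seen here) normalizes tortuosity and
  the skeleton length.
- a **polar boundary profile** r(θ): 360 rays from the centroid; the
  boundary is the 0.5-level set of the bilinearly interpolated mask
  indicator, located by scanning at 0.125-px steps with linear sub-step
  refinement. For non-star-shaped boundaries the farthest crossing is
  used. On a rasterized disc the recovered radius is within ±0.5 px of
  truth, the worst case allowed by pixelation.

From these: AR = a/b; DWR = axial over lateral bounding-box extent;
RV = std/mean of r(θ); tortuosity = Crofton boundary perimeter over the
equivalent-ellipse perimeter (the Crofton estimator is used because
marching-squares contour length overestimates smooth boundaries by
several percent); ENS = medial-axis skeleton length over the
equivalent-ellipse perimeter. Skeletonization uses Lee's method, which we
found substantially more rotation-stable than the default thinning
(skeleton pixel counts agreed within ~5% across 90° rotations versus
~20% divergence for the alternative); length counts orthogonal links as 1
and diagonal links as √2, skipping diagonals that short-cut an orthogonal
two-step.

Intensity features compare bands of width `band_px` (default 5 px, an
empirically reasonable margin scale for clinical sonograms; exposed in
config) on either side of the boundary:

- BD = mean(outer band) − mean(inner band). Benign masses with crisp
  margins score high BD; the phantom suite asserts this direction.
- MS = mean over 360 boundary samples of |I(x + b·n) − I(x − b·n)|, the
  absolute intensity difference `band_px` outside vs inside along the
  local outward normal. Normals come from a ±3-sample tangent stencil;
  a 1-sample stencil is dominated by sub-pixel rasterization jitter.
  For an edge blurred into a linear ramp wider than `2·band_px`, MS
  equals ramp slope × 2·band_px; for sharper edges it saturates at the
  full margin contrast. MS therefore decreases monotonically with margin
  blur, which is the diagnostically relevant behavior.
- AVI / AVM = the standard deviation over 36 equal angular sectors
  (config `n_sectors`) of, respectively, the mean interior intensity and
  the mean per-sector margin sharpness. Population (ddof = 0) standard
  deviations are used.

Per-mass values are arithmetic means over the mass's 1–10 ROIs.

## Color-Doppler features

The rendered color-bar is sampled into 100 equally spaced swatches per
flow direction; level ℓ carries velocity index v(ℓ) = ℓ/100 (fraction of
the bar's vmax), so v is strictly increasing with v(100) = 1. A pixel is
Doppler signal iff its RGB distance from the gray axis exceeds
`chroma_thresh` (default 20 on 8-bit RGB, which separates gray B-mode
speckle from color overlay in both synthetic and typical clinical
frames). Each colored pixel takes the level of its nearest swatch by RGB
Euclidean distance; exact ties resolve to the lower level. Both flow
directions map to the same nonnegative index — the features quantify
vascularity, not direction.

VFA = 100 × (colored ROI pixels)/(ROI area). VI defaults to the mean
velocity index over *colored* ROI pixels, which is consistent with the
reference cohort's VI scale (benign 0.42 ± 0.58, malignant 0.85 ± 0.64);
a `vi_denominator="roi"` switch averages over all ROI pixels instead,
since some vascularity indices normalize that way. VFA is invariant to
vmax; VI is in index units, so rescaling the bar's vmax changes physical
velocities but not VI.

## Classifier

Naive Bayes (categorical attributes) and logistic regression (numeric
attributes) are combined by a **single** boost step rather than iterated
boosting: both constituents are already strong, and one step lets the
first stage flag its problem cases for closer examination by the second
without the over-fitting risk of a long heterogeneous boosting run.

- NB: weighted class priors; Laplace add-1 smoothed weighted category
  frequencies over the categories observed in training. Weights act as
  fractional case counts, making a weight-2 case exactly equivalent to a
  duplicated case. Missing categories are skipped in the likelihood
  product, so missing BI-RADS needs no imputation.
- LR: features standardized to weighted zero mean / unit SD computed on
  the training cases only; zero-variance features dropped; a ridge
  penalty of λ = 1e-8 keeps separable problems finite. Effect sizes are
  reported as standardized directionless odds ratios exp(|β|) with a
  sign tag.
- Boost: stage 1 (NB by default, configurable) trains on uniform
  weights; ε₁ = its weighted 0.5-threshold error, clamped to
  [1e-6, 0.5]; α₁ = ½·ln((1−ε₁)/ε₁); weights are multiplied by
  exp(±α₁) (up for misclassified), renormalized to sum 1, and stage 2
  trains on them; α₂ likewise from stage 2's error on its own training
  weights. Output p = (α₁p₁ + α₂p₂)/(α₁+α₂) — an α-weighted probability
  average rather than discrete voting, because ROC analysis and
  confidence pruning need a graded score. If both α are 0 the stage with
  the lower training error is used alone; if an attribute group is
  empty the ensemble degenerates to the other constituent.
- Missing age is imputed with the mean of the observed ages — computed
  inside each training fold and applied to that fold's test case, never
  globally.

## Resampling and evaluation

SMOTE balances the training data to class equality: each synthetic case
interpolates a uniformly chosen minority case toward one of its k = 5
nearest minority neighbors (Euclidean in standardized numeric space) at
u ~ U(0,1); BI-RADS is copied from the seed case, never interpolated.
Synthetics carry a `synthetic` flag, are regenerated inside every LOOCV
training fold with a fold-indexed seed fanned out from the master seed,
and are never scored — the leakage guard is asserted in tests.

ROC: Mann–Whitney AUC with ties counted ½; SE/CI and paired AUC tests by
DeLong's method in the midrank formulation (implemented here and
cross-checked in tests against exhaustive pair counting and closed-form
toy cases). The Youden point maximizes Se + Sp − 1 with ties resolved
toward higher sensitivity — missing a cancer costs more than a false
alarm — and specificities at fixed sensitivities of 95% and 98% are
reported from the largest threshold attaining each target. Drop-rate
pruning removes round(rate × n) cases (half rounds up) with the smallest
|p − 0.5|, extending over any cases tied at the boundary confidence, and
re-summarizes the remainder; a single-class remainder is flagged
undefined rather than scored.

## Phantom simulator

`make_lesion_image` draws a boundary r(θ) = R(1 + ε·cos kθ), scaled
anisotropically, filled with a hypoechoic interior on a brighter
background, Gaussian margin blur, and multiplicative Gaussian speckle.
The analytic boundary doubles as the ROI polygon and yields closed-form
ground truth (RV = ε/√2 for isotropic scaling; AR from exact polygon
second moments; DWR from the polygon bounding box; BD from the nominal
contrast). `make_doppler_frame` paints vessel tracks with exact palette
swatches (a blue-to-red ramp keeping every level strongly chromatic) and
renders a 200-px 100-swatch bar whose extraction round-trips exactly.

`simulate_cohort` draws each numeric feature from an independent
class-conditional Gaussian truncated at physical bounds (VFA, VI, RV,
ENS ≥ 0; AR, tortuosity ≥ 1; MS in [0, 255]; ages in [18, 95]); the
default means/SDs are the reference cohort's published class-conditional
statistics, with 95 benign and 64 malignant cases and 3 ages masked
missing. Only marginals are published, so features are independent per
class by design; a correlation-matrix hook (Gaussian copula over the
truncated marginals) exists for sensitivity studies but is off by
default — we do not invent covariance. For strongly truncated features
(VI, VFA, whose lower bound sits within one SD of the mean) the
realized mean exceeds the nominal one; tests therefore validate sample
means against the analytic truncated-normal mean. BI-RADS is drawn from
the cohort's category frequencies (0:12, 1:6, 2:9, 3:4, 4:66, 5:38,
24 missing) split into fixed per-class counts such that categories 4–5
skew malignant while the BI-RADS-only model remains a weak baseline
(LOOCV AUC ≈ 0.6, matching its role as the low anchor of the feature-set
ordering).

What the simulator does *not* emulate: physical speckle statistics
(k-space convolution), attenuation/shadowing, inter-feature correlation,
scanner-specific color maps, or reader variability in ROI placement.
Passing phantom tests therefore demonstrates the correctness of the
extraction and modeling machinery and the qualitative feature-set
ordering — not clinical performance. The published clinical AUCs were
measured on 159 non-public images; on simulated cohorts with independent
marginals the full-feature LOOCV AUC lands near 0.90–0.94 rather than
0.958, and the suite asserts only the ordering (full set beats the
clinical baseline; adding color-Doppler to grayscale does not reduce
AUC; the boosted ensemble is not worse than either constituent by more
than 0.02) over 3 seeded replicates at the study's n = 159.

## Problem sizes and runtime choices

Unit geometry runs on 64–256 px canvases; the phantom round-trip grid
uses 20 lesions at 224 px; cohort-level properties use study-sized
(n = 159) simulated cohorts with 3 seeds in the test suite and 2
replicate draws in `scripts/acceptance.py`. These sizes give stable
Monte-Carlo estimates (AUC SE ≈ 0.02–0.03 per draw) while keeping the
full suite and the acceptance script each within a few minutes on one
CPU.

## Known limitations

- MS is reported in raw 8-bit intensity units over the sampled span; its
  absolute scale depends on `band_px` and is comparable only within a
  fixed configuration.
- ENS depends on the skeletonization method; Lee's method is fixed for
  reproducibility, and values from other thinning algorithms are not
  interchangeable.
- The boundary profile assumes the centroid lies inside the mask;
  strongly non-star-shaped ROIs resolve to the outermost crossing, which
  under-represents deep concavities.
- The single-boost ensemble supports more than two constituents in code,
  but only the NB→LR two-stage configuration is validated.
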