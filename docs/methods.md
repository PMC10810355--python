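# Methods

## The measurement problem

A binary FAZ mask is a raster approximation of a smooth anatomical region.
Every descriptor except area depends on boundary geometry, and a raster
boundary is only defined up to about half a pixel, so the package is built
around one principle: measure boundary quantities on a sub-pixel contour,
and validate every raster measurement against an exact analytic oracle.

### Contours

`trace_contour` takes the 0.5 iso-level of the mask indicator after
mollifying it with a Gaussian of σ = 1 pixel. The raw marching-squares
contour of a hard binary grid staircases at the half-pixel scale and
overestimates the perimeter of a smooth shape by ~6% (enough to turn a
circle's compactness into 0.89); contouring the band-limited field instead
recovers digitized-disk perimeters to under 0.5% from radius 20 px up,
without changing the enclosed region materially. Masks too small to reach
the 0.5 level after smoothing (worst case: a single pixel) fall back to
the raw iso-level, so degenerate inputs still produce a valid polygon (a
single pixel gives the minimal diamond, perimeter 2√2 px). This is a
mollification of the input field, not a spline fit of the contour.

### Area

Area is deliberately *not* the contour polygon's area: it is the
foreground pixel count times the per-pixel area constant
`c = pixel_height × pixel_width`, the standard raster definition. The two
measures differ by O(perimeter · pixel); for disks of radius ≥ 40 px the
difference is under 2%.

### Solidity and the clamp tolerance

Solidity divides a pixel-count area by a polygon-hull area, so
discretisation can push it marginally above 1 for convex shapes. The ratio
is clamped to 1 within a scale-aware tolerance
`max(0.01, pixel_diag · p_cvh / Area_cvh)` — the expected size of the
mixed-measurement mismatch — and anything beyond that raises an
internal-consistency error rather than silently passing a value that
violates the definition. The analytic-polygon route uses a strict 1e-9
tolerance.

### Eccentricity

The longest/shortest straight-line extents `a ≥ b` are implemented as
maximum and minimum Feret (caliper) diameters of the contour's convex
hull: the max is the largest pairwise hull-vertex distance, the min is the
smallest projection width over hull-edge normals (the rotating-calipers
identity). A moment-based (inertia-ellipse) reading was considered and
rejected: for shapes dominated by third and higher harmonics the inertia
tensor is isotropic, so moment eccentricity collapses to 0 for visibly
non-circular shapes, while the caliper reading degrades gracefully.

One caveat is intrinsic to the formula, not the carrier:
`ecc = √(1 − (b/a)²)` has an unbounded derivative at `b/a = 1`, so *no*
estimator of eccentricity from a raster is relatively accurate near
circularity. Agreement checks against the oracle therefore state their
tolerance on the axis ratio `b/a` (measured: within 2.5% of the oracle at
256² grids), and downstream consumers should treat small eccentricities as
qualitatively "near-circular" rather than as precise values. The other
four descriptors agree with the oracle to well under 5% relative at 256².

## The synthetic cohort

Real FAZ datasets with amyloid-confirmed labels are access-restricted, so
the pipeline is exercised end to end on a simulator whose ground truth is
known and controllable.

Shapes are Fourier-radius contours
`r(θ) = r0 · (1 + Σₖ aₖ cos(kθ + φₖ))`, k = 2…6, with
`Σ|aₖ| < 0.9` guaranteeing a positive radius and a simple (star-shaped)
curve. The family spans near-circular to irregular contours with few
parameters, and — crucially — admits an exact oracle: shoelace area, exact
polygon perimeter, Qhull convex hull and a 0.05°-step rotation-scan Feret
measurement on a dense (1440-vertex) analytic polygon, sharing no code
with the raster path.

Per class, `r0` is log-normal; amplitudes are half-normal with scale
`irregularity / k`; phases uniform; age normal; sex Bernoulli. Defaults
(per 3×3 mm scan at 256², i.e. 11.7 µm pixels):

| parameter | NC | AD | rationale |
| --- | --- | --- | --- |
| median FAZ radius r0 | 0.275 mm | ≈ 0.289 mm (+0.28 SD on log scale) | typical superficial-plexus FAZ ≈ 0.3 mm²; modest enlargement in AD so area alone is a weak classifier |
| log r0 SD | 0.18 | 0.18 | large normal variation in FAZ size |
| irregularity | 0.06 | 0.09 | boundary irregularity carries most of the class signal |
| age (years) | 68.0 ± 7.1 | 65.7 ± 7.9 | overlapping memory-clinic profile; a correction covariate, not a dominant predictor |
| male fraction | 0.285 | 0.45 | idem |

The effect sizes were calibrated once so that the seven-input model
reaches a cross-validated AUC in the low 0.7s at n = 85 — the operating
regime the evaluation protocol is designed around — while the area-only
baseline stays in the low 0.6s. Cohort sizes default to 31 AD / 54 NC
(training) and 29 AD / 16 NC (holdout).

What the simulator does **not** emulate: OCTA speckle and vessel texture
(`synthetic_octa_image` provides only a two-level intensity contrast for
segmenter smoke tests), segmentation errors, inter-eye correlation within
a subject, scanner differences, or comorbidity covariates. Passing tests
therefore demonstrate that the measurement and evaluation machinery is
correct and unbiased under a known generative truth — not that any
particular clinical performance level transfers to real data.

## Classification and evaluation

Feature vectors are the selected shape descriptors in subset order,
followed by age and sex (trees are scale-invariant, so covariates enter
raw). Model families are LGBM, XGBoost and random forest with library
defaults and fixed seeds — no tuning protocol is applied, which keeps
subset and family comparisons honest. Note that boosted-tree defaults
(minimum 20 samples per leaf) make models on fewer than ~60 records
degenerate to constant predictions.

Folds are stratified by label (at n = 85 with a 31/54 imbalance,
unstratified folds can degenerate) and shared across feature subsets so
ablation comparisons are paired. Splitting is per record; if both eyes of
a subject are present, a group-aware split is the methodologically safer
choice and can be built by passing a custom `FoldSplit`. Records with
missing covariates are rejected, not imputed; class imbalance is left
unweighted.

AUC is the trapezoidal area under the ROC curve (one point per distinct
threshold), which the test suite requires to match brute-force
Mann–Whitney pair counting (ties = ½) to 1e-10. Threshold metrics use the
inclusive rule "AD iff probability ≥ t" with t = 0.5 by default.
Sensitivity and specificity are reported as undefined (`None`) when a
class is absent, never as 0. The operating-point search returns the
largest threshold whose sensitivity meets the target, i.e. the most
specific model that achieves a screening-grade sensitivity. Paired fold
AUCs are compared with a two-sided paired t-test, isolated behind one
function so an exchangeable test (e.g. DeLong) can be substituted; the
degenerate cases (identical folds → p = 1; constant non-zero shift →
p = 0) are handled explicitly.

Two protocol-level safeguards are tested rather than assumed. First, an
identifier-level audit refuses any holdout evaluation whose train and test
sets share record ids. Second, a null-cohort control draws both classes
from the same distribution and requires cross-validated AUC to stay in
[0.40, 0.60]; this control runs at 200 subjects per class because at
n = 85 cross-validated AUC under the null is noticeably *pessimistic*
(finite-population anticorrelation between training and held-out folds,
observed as low as 0.32 with flexible boosters) — a small-sample artifact,
not leakage, and one worth knowing about when reading small-cohort CV
results anywhere.

## Segmentation

Learned FAZ segmentation is out of scope by design; the package defines
the contract a segmenter must satisfy (same-shape binary mask,
deterministic, single hole-free component) plus a conformance checker
usable against third-party plugins, and ships a classical reference
segmenter: percentile threshold within the central window, small binary
closing, centre-nearest connected component, hole filling. On synthetic
dark-disk images at 320² it reaches Dice ≈ 0.98 against the generating
disk. It is a smoke-test stand-in, not a clinical tool.

## Numerical and I/O choices

All geometry is computed in mm using the raster convention
`(x, y) = (col·pixel_w, row·pixel_h)`; polygons are normalised to positive
(counter-clockwise) orientation. The default pixel scale assumes the 3 mm
scan field divided by the raster side, overridable everywhere. Numeric
output is serialised at 6 significant digits with sorted JSON keys, so
reruns under the same manifest are byte-identical — this is asserted in
the test suite, not just intended. Simulation-heavy checks are sized to
keep the full suite in the minutes range (e.g. 20-seed protocol
repetitions, 200-shape oracle sweeps); the cohort sizes used are stated in
each test.

## Known limitations

- Descriptor accuracy degrades below ~10 px FAZ radius; the 3 mm / 256²
  default keeps typical shapes at 20–35 px where measured errors are ≤2%
  (≤2.5% axis ratio).
- Eccentricity near 0 is ill-conditioned (see above).
- The simulator's class structure is a design instrument, not an
  epidemiological model; absolute AUCs on synthetic cohorts are
  calibration artifacts.
- Single-feature and ablation results at n = 85 have fold-level SDs of
  5–15 AUC points; single-seed orderings among the four shape descriptors
  are not stable and only multi-seed directions are meaningful.
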