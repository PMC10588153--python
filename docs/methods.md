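# Methods

## The measurement model

An islet in a section is idealised as a simple closed outline in the
specimen plane, calibrated in µm.  Four descriptors summarise it:

* **area** *A* (µm²),
* **perimeter** *P* (µm),
* **maximum Feret diameter** (µm) — the largest caliper distance across
  the outline, implementing "maximum diameter" (the alternative reading,
  the major ellipse axis, is not used; the choice is flagged here because
  the two differ for lobulated shapes),
* **circularity** *C* = 4π·A/P², dimensionless, 1 for a circle
  (isoperimetric maximum) and lower for irregular or lobulated outlines.

Per specimen, the analysis reduces the islet population to: islet count;
count per cm² of parenchyma; total islet area (cm², with 1 cm² = 10⁸ µm²
exact); total area as % of parenchyma; mean maximum diameter over islets;
the number of islets with *C* strictly below the diagnostic threshold
(default 0.71), raw and per cm²; and the number of "islet clusters"
(area strictly > 100,000 µm², a size class that occurs in normal pancreas
too and is therefore flagged rather than excluded).

Boundary conventions follow the printed inequalities: `<` for low
circularity, `>` for clusters, `≥` for the cytology measurement cut-offs
(nucleus 9 µm, nucleolus 1.5 µm), `>` for the diagnostic-criteria flags
(nucleus 15 µm, nucleolus 5 µm).  Group values are means of per-specimen
values, not pooled ratios — this is the convention under which the
published density row (≈ mean count / mean parenchyma area) is internally
consistent.  Average cell size is implemented as islet area divided by
cell count (µm²/cell); the source text verbally defines the reciprocal
but reports a size, so the reciprocal reading is treated as a typo.

## Raster measurement

Label masks carry one positive integer per islet and an isotropic
microns-per-pixel scalar supplied by the caller (never read from
proprietary slide headers).  Islet components are 8-connected, background
4-connected, and holes inside a component are filled before measurement
(the outline, not internal gaps, is the object).

* **Area** is the hole-filled pixel count × mpp².
* **Perimeter** comes from the marching-squares sub-pixel boundary contour
  smoothed with a 5-sample circular moving average (samples are ~0.7 px
  apart, so the window spans ~3.5 px of boundary).  Raw marching-squares
  length overestimates smooth contours by ~5% (staircase bias) and naive
  boundary-edge counting by up to ~27%; few-direction Crofton estimates
  are anisotropy-biased on straight axis-aligned edges (a 4-direction
  Crofton underestimates a digital square's perimeter by ~5.5%, which
  would inflate its circularity to ~0.88 against the true π/4 ≈ 0.785).
  The smoothed-contour estimator was measured at +0.1% (disk r = 50 px),
  −1.0% (100 px square) and +0.3% (lobulated contour ~300 px across),
  within the package's accuracy targets of ≤1% area and ≤2% perimeter
  error for objects ≥200 px across.
* **Maximum Feret diameter** is the maximum pairwise distance over the
  convex hull of the same smoothed contour — keeping all three boundary
  measurements on one boundary estimate (the pixel-corner hull would
  overestimate a 100 px disk by ~2.6%).
* **Circularity** is computed from these two estimates and deliberately
  **not clamped** at 1: discretisation can push it slightly above 1, and
  recording the raw value keeps threshold comparisons honest.  Exact
  polygon circularity obeys C ≤ 1 + 1e−9.

Small-object floor: "islets of any size" cannot be honoured literally on
rasters without admitting single-pixel noise; extraction applies a default
minimum of 5 pixels (5·mpp² µm², configurable down to 1 pixel).
Border-touching components are included but flagged, so users can exclude
them — whether the original analysis did is unknown.

## Statistics

The sole inferential tool is the unpaired two-sample t-test with pooled
variance, df = n₁+n₂−2, two-tailed — the spreadsheet "equal variance"
test.  It is computable from printed (mean, SE, n) triples by recovering
SD = SE·√n; this route reproduces the published p-values (0.023 for the
low-circularity count, 0.50 for islet number, 0.64 for total area, 0.833
for area fraction) to their printed precision, which is itself the
evidence that the equal-variance form (not Welch) was the published
procedure.  The density and diameter rows recompute to 0.81 and 0.90
against printed 0.80 and 0.89 — last-digit discrepancies attributable to
the rounding of the printed summaries they are recomputed from.

**Threshold scan.**  "The value generating the largest statistically
significant difference" is operationalised as the minimum two-tailed p for
the per-cm² low-circularity density over a grid of candidate thresholds
(default 0.50–0.95, step 0.01; the source states no grid), ties resolved
toward the smaller threshold, candidates with zero variance in both groups
skipped with a logged warning.  No multiple-testing correction is applied
across the ~46 dependent candidates, matching the original procedure; the
resulting selection bias is quantified (under a null cohort the median
selected p falls well below 0.5 — see the test suite) rather than
corrected.

**Interobserver statistics.**  Per-rater accuracy is the percentage of
correctly classified slides.  The combined rate over both experience
groups uses the size-weighted grand mean, and its SE is reconstructed from
the total sum of squares: within-group SS recovered from the group SEs
plus between-group SS, divided by N−1, then √(var/N).  Applied to the two
published rater-group summaries this yields 49.0% ± 5.43% and p = 0.83.
Individual rater scores are not published, so only this summary-level
reproduction is claimed.

## The synthetic cohort generator

No per-islet data were deposited, so the pipeline is exercised on
synthetic specimens.  An islet outline is a single-harmonic polar contour
r(θ) = R·(1 + a·cos(kθ + φ)) with k lobes of relative amplitude a, plus
two low-order random cosine harmonics of relative amplitude ≤ 1% (smooth
jitter).  This is the simplest family whose circularity is analytically
controllable: area is πR²(1 + a²/2) in closed form and the perimeter
integral is evaluated by adaptive quadrature, giving an oracle
`expected_circularity(k, a)` (tolerance 1e−12, small-a limit
1 − a²(k²−1)/2) that is independent of the polygon and raster measurement
paths and is inverted to place each simulated islet at a drawn target
circularity.  Fourier-mixture outlines would be the natural extension.

Per specimen the generator draws: islet count (Gaussian truncated at 1,
rounded), parenchyma area (Gaussian truncated at half its mean), base
radii (lognormal — right-skewed islet sizes), lobe counts (uniform
integers 3–8), and target circularities from a two-component mixture:
a "round" component uniform on (0.72, 0.98) and a "lobulated" component
uniform on (0.40, 0.70), with group-specific lobulated weight.  One root
seed spawns one child stream per specimen, so outputs are byte-identical
under a fixed seed and adding a specimen never perturbs earlier ones.

### Calibration of the study-scale preset (`table3_like`)

The published study is the study design (4 ANHH vs 5 control specimens)
plus group summaries; the preset is moment-matched to them:

| parameter | ANHH | control | source |
|---|---|---|---|
| islet count mean ± SD | 417 ± 135.6 | 501 ± 201.2 | printed mean ± SE·√n |
| parenchyma (cm²) | 1.99 ± 0.166 | 2.47 ± 0.619 | printed mean ± SE·√n |
| lobulated weight | 82/417 ≈ 0.197 | 30/501 ≈ 0.060 | printed low-circularity fractions |
| radius lognormal (µ, σ) | (3.7059, 0.5492) | (3.7131, 0.5351) | moment matching, below |

Radius parameters come from matching E[maximum diameter] (107 / 105 µm)
and E[islet area] (total area / count) through Monte-Carlo estimates of
the shape factors E[feret/(2R)] and E[area/(πR²)] under each group's
(k, a, jitter) distribution (`shape_moment_factors`, 20,000 samples);
with R independent of shape both group means factorise exactly through
these factors.  Averaged over 200 replicate cohorts, every published group
mean (count, density, total area, area fraction, diameter,
low-circularity count) is reproduced within two printed SEs — the
property-based surrogate for data that cannot be re-measured.

Cytology distributions (nucleus ~N(8.0, 1.8) vs N(7.0, 1.2) µm, visible
nucleolus fraction 0.45 vs 0.15, nucleolus ~N(2.2, 0.8) vs N(1.8, 0.5) µm,
~90 µm² per cell) are **not** constrained by the main published text; they
are one-time plausible choices that reproduce the qualitative pattern
(higher recognizable-nucleolus fraction in ANHH, no marked cell-size
difference).

### Other presets

* `render_demo` — the same two-group structure scaled for rasterisation:
  ~12 islets per specimen, 0.02 cm² parenchyma, islet radii ~75 µm so
  every islet spans >100 px at mpp = 1.  Chosen because at ≥100 px per
  islet diameter the raster measurements track the polygon oracle within
  2% (area) and 0.05 (circularity), the regime the round-trip checks use.
* `planted_threshold` — both groups exchangeable except for extra ANHH
  lobulated mass confined to (c*−0.04, c*−0.01) just below a planted
  cut-off c* (default 0.71), at the study-scale total effect (ANHH
  low-circularity fraction ≈ 0.197 vs 0.060).  Below the band the groups
  are identical and above it the difference is constant while variance
  grows, so the scan's minimum-p threshold concentrates at c*; the
  recovery rate (within ±0.05 in ≥90% of 100 seeded cohorts) is checked
  under this configuration.  Note that under a *broad* lobulated contrast
  (as in `table3_like`) both the group difference and its SD scale
  together as the threshold moves, the p-curve is nearly flat over the
  lobulated range, and the selected threshold legitimately scatters — an
  instructive property of minimum-p threshold selection, not a defect.

### Rendering

A specimen renders to an integer label mask plus a binary tissue mask.
The tissue region is a centred disk whose pixel count equals
parenchyma/mpp² exactly (pixels chosen by rank distance from the centre),
so parenchyma area survives the raster round trip to machine precision.
Islets are packed by rejection-sampling centres with non-overlapping
bounding circles (largest first); packing failure raises an explicit
canvas-too-small error rather than silently overlapping islets.

## What the synthetic data do and do not show

The generator reproduces the *summary-level* statistical structure the
analysis consumes: counts, size scale and skew, circularity mixture, group
contrast and specimen-to-specimen variability.  It does not emulate real
histology: no staining or imaging noise, no touching/overlapping islets,
no spatial clustering, no ductuloinsular complexes, no section artefacts,
and circularity distributions within groups are a modelling choice (only
the thresholded counts are constrained by the published numbers).  Passing
round-trip and calibration tests therefore validates the measurement and
inference machinery, not the segmentability of real slides; real WSI
segmentation quality is out of scope (users supply label masks).

## Numerical choices and degenerate inputs

* Sizes used by the shipped experiments: 200 replicate cohorts for the
  calibration averages, 100 seeded cohorts for scan recovery, 10,000
  summary-level null cohorts for type-I calibration (the pooled test's
  rejection rate at α = 0.05 is 0.05 ± 0.01 there); a separate 300-cohort
  small-scale full-generator null check guards against gross
  anticonservatism.
* Zero variance in both groups: equal means → t = 0, p = 1 by convention;
  unequal means → explicit degenerate-input error.  Groups with fewer
  than 2 specimens are rejected.
* An empty specimen summarises to zeros (valid); an empty tissue mask is
  an error because densities would be undefined.
* Polygon validity (≥3 distinct vertices, simplicity) is checked via
  shapely on user-facing paths and skipped inside the generator, whose
  star-shaped contours are simple by construction.
* Circularity inversion uses a dense precomputed monotone (a → C) table
  per lobe count (quadrature at 180 nodes, linear interpolation, ~1e−4
  accuracy), clamping unattainable targets to the range endpoint.

## Known limitations

* The perimeter estimator is a documented package choice; the original
  image-analysis software's estimator is proprietary and unpublished, so
  absolute circularities from other software may differ slightly near the
  0.71 threshold even on identical masks.
* "Maximum diameter" and the handling of border-touching islets in the
  original study are interpretations (flagged above and in the record
  schema).
* Summary-level reproduction of published statistics inherits the
  rounding of the printed inputs (last-digit differences in two p-values).
* The cytology module operates on measured diameter lists; it does not
  detect nuclei or nucleoli in images.
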