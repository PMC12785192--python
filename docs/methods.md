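# Methods

This note documents the quantitative procedures implemented in
`cotyquant`, the parameters that matter, what the synthetic-image
generator does and does not emulate, and the design choices made where
the procedure was genuinely open.

## Necrosis quantification

**Color space.** Trypan-blue-stained (dead) pixels are selected in HSB
space with every channel scaled to 0–255, the convention of interactive
color-threshold tools. With `M = max(r,g,b)`, `m = min(r,g,b)`:
brightness is `M`; saturation is `round(255·(M−m)/M)` (0 at black); hue
is the hexagonal hue fraction in [0,1) (red 0, green 1/3, blue 2/3)
scaled by 255 and rounded half-up, 0 for achromatic pixels. All six box
bounds are treated as **closed** intervals, matching lower/upper slider
semantics; hue wraparound across 0/255 is not supported (the default
blue window, 120–200, does not need it), and constructing a threshold
with `lo > hi` is an error.

**Size filters.** Components are 8-connected by default (diagonals
join, the common particle-analysis behavior; 4-connectivity is
available). Total dead area sums components with area ≥ 20 px; the
largest necrotic spot is the maximal component with area ≥ 1000 px,
chosen so a "spot" comprises several neighboring dead cells (~100–200 px
per cell at the reference magnification). Both floors are read
**inclusively** (≥); a `strict` flag gives the `>` reading, since
size-filter wording is ambiguous between the two. Ties at the maximal
area break toward the smallest label (top-most, left-most component), a
deterministic convention. Centroids are unweighted pixel-coordinate
means; holes inside a stained spot are not filled.

Pixel-area floors are magnification-dependent: when images are rendered
or analyzed at a different frame size, the floors should be scaled by
the frame-area ratio. The reduced-size Monte-Carlo tests (256 px frames
against the 384 px reference) accordingly use floors of 9 and 444 px.

## Cotyledon morphometry and lesion position

**Ellipse fit.** The cotyledon mask (supplied, or obtained by Otsu
thresholding of brightness against the pale background, keeping the
largest component and filling holes) is summarized by its second-moment
ellipse: center = coordinate mean; from the 2×2 central second-moment
matrix with eigenvalues λ₁ ≥ λ₂, raw semi-axes are 2√λ₁ and 2√λ₂ —
exact for a filled continuous ellipse — then both are rescaled by
√(A/(π·a₀·b₀)) so the ellipse area equals the pixel count (area-matched
"equivalent ellipse"). The angle comes from the principal eigenvector,
mapped to [0, 180) measured counterclockwise on screen from +x. Fits on
rasterized ellipses with a = 30–120 px recover semi-axes within 2% and
angle within 2°; the area-match ratio π·a·b/A is 1 to within 0.5% by
construction. Degenerate inputs: fewer than 5 pixels or collinear masks
raise; equal eigenvalues (a disk) report angle 0 with a `circular` flag.

**Normalized position.** Input images are pre-rotated base-down, so the
tip is "up". The spot centroid is translated to the ellipse center and
projected on the major/minor axes; the major-axis orientation pointing
up is used, which for a roughly upright leaf is the alignment rotation
of magnitude ≤ 45° (leaves tilted further are flagged, not dropped).
`y_rel` is the tip-positive component divided by the major radius;
`x_rel` the screen-right-positive component divided by the **minor**
radius, so both coordinates are fractions of their own radius and the
ellipse boundary is the unit circle. Because the source convention only
fixes the y normalization ("major radius = 1"), `x_norm="major"` is
available for sensitivity analysis. Cotyledons with no component at or
above the spot floor have no position, by design; they still contribute
to area-based tables.

## Callose quantification

Square confocal fields are partitioned into a 3×3 grid with floor-based
half-open tiles (every pixel in exactly one tile); only the center tile
is counted, at a single global intensity floor. The floor is calibrated
on no-stain control images (autofluorescence only): it is the smallest
integer T such that the pooled-control fraction of pixels ≥ T is at
most ε (default 10⁻⁴). This makes the guarantee explicit: by
construction the training exceedance is ≤ ε, and on held-out controls
from the same distribution it stays ≤ 2ε on average. Supra-threshold
8-connected components with area ≥ 2 px count as puncta (the 2-px floor
suppresses single-pixel shot noise; set 1 for strict literalism);
components touching the tile border count. Density is count divided by
the tile area in mm², from the per-image pixel size — carried per image
so that mixed magnifications are handled. Representative images per
condition are those whose count equals the group's lower median.

## Statistics

Measurements are pooled across experiment replicates (a blocked variant
is deliberately out of scope; replicate is carried in the tables for
inspection). Per Ca condition:

* **ANOVA**: ordinary least squares of the response on categorical day,
  genotype and their interaction, with **sequential (Type I)** sums of
  squares in that order — the default of the common statistical
  environments for this design; Type II ("marginal") is available
  behind a flag for sensitivity analysis on unbalanced data. Day is a
  factor, not a covariate, because growth days are discrete groups. The
  sequential decomposition satisfies ΣSS(terms) + SS(residual) =
  total centered SS to 10⁻⁸ relative, verified against an explicit
  design-matrix least-squares oracle.
* **t-tests**: two-sided pooled-variance (Student) two-sample tests per
  (Ca, day) cell, df = n₁+n₂−2 — "Student" is taken literally rather
  than Welch — with stars `*` p<0.05, `**` p<0.01, `***` p<0.001.
  No multiple-testing correction is applied across cells, matching the
  source analysis design.
* **Representative selection**: per (genotype, Ca, day) group, the
  sample minimizing √[(area−m_area)² + (x−m_x)² + (y−m_y)²] about the
  group medians, on raw values as literally specified. Raw areas
  (thousands of px) dominate the unit-scale coordinates, so a
  standardized variant (deviations divided by the group median absolute
  deviation, zero-MAD components left unscaled) is provided behind a
  flag. Ties break toward the smallest image id.
* Degenerate inputs (zero-variance response, undersized cells) yield
  flagged NaN rows or logged skips, never exceptions, so cohort sweeps
  complete.

## Synthetic data

The generator emulates the features the pipeline measures and nothing
more: an elliptical leaf (pale lamina, optional darker midvein streak)
on a near-white background, circular lesions whose RGB color maps
strictly inside the stain box while leaf/vein/background map outside,
and dark-field images with Gaussian-profile puncta over sub-threshold
autofluorescent blobs (blob profiles compose by maximum so clean-image
peaks are bounded). Ground truth is defined **at the observable level**:
touching lesions are recorded as the merged component a perfect
segmenter would see, and the true puncta count is the number of
supra-threshold components in the clean center tile. With zero noise
and in-box stain colors, pipeline output equals ground truth exactly —
pixel for pixel — which is what the exact-recovery tests assert.
Additive per-channel Gaussian noise (clipped to [0,255]) stresses the
thresholds; area-recovery error grows continuously with noise sd up to
at least 8 on 8-bit images.

Simulated cohorts draw, per cotyledon: leaf geometry (semi-major axis
31–36% of the frame, aspect 0.52–0.62, tilt ~N(0°, 6°) clipped to
±15°); total lesion area lognormal (log-mean log 3000 px at the
384-px-frame reference leaf, log-sd 0.3, +0.15/day trend, capped at 35%
of the lamina); a clipped-normal largest-lesion share; and a Poisson
number of secondary lesions splitting the remainder (Dirichlet). Two
properties of the lesion sampler matter for valid statistics and were
chosen deliberately:

* **Resolution invariance** — area laws scale with the rendered leaf
  area, so a cohort rendered at 256 px is the same *study* as one at
  384 px, only coarser.
* **Area-law conservation across genotypes** — lesions are placed by
  rejection sampling toward non-overlap (distinct spots, as in stained
  material), positions are shrunk toward the center only as far as
  containment requires, and oversized secondary pieces are split rather
  than truncated. Without these, genotype-dependent overlap and
  truncation losses would leak a spurious genotype effect into "equal
  total area" cohorts; with them, the genotype-term null calibration
  holds (p-values uniform, ~5% false positives at α = 0.05).

Default genotype effects mirror the biological contrast under test:
identical total-area laws; largest-lesion share 0.45 (wild type) vs
0.70 (mutant); tip-biased placement, truncated-normal y_rel with mean
0.6, sd 0.2 (wild type) vs mean 0.15, sd 0.35 (mutant); callose puncta
means 3 + 2.5/day (wild type) vs 1 + 0.8/day (mutant) under low Ca,
collapsing to ~0.3 under 2 mM. Positional laws are specified in
ellipse-normalized coordinates, making them leaf-size-invariant — the
same property the measured statistic has. Child seeds derive
deterministically from the master seed and the (genotype, day, Ca,
replicate) index; corpora are byte-identical under a fixed seed.

The generator does **not** emulate: petioles and non-elliptical leaf
outlines, chromatic staining variability, uneven illumination,
anti-aliased edges, optics (PSF, z-structure), or growth of leaf shape
across days. Passing tests therefore demonstrate correctness of the
measurement and inference chain on images whose difficulty lies in
geometry, color thresholds, counting statistics and sampling noise —
not robustness to the photometric artifacts of real micrographs, which
the QC-exclusion path (e.g. bubbles) and manual masks are for.

## Problem sizes and numerical choices

Unit and property tests run on small instances; the Monte-Carlo checks
use 256-px frames with 32 images per null cohort (100 cohorts), 60
images per effect cohort (50 cohorts) and floors scaled as described
above — sizes chosen so the full suite completes in a few minutes while
leaving the test statistics well-powered. Labeling is validated
exhaustively against a flood-fill oracle on all 65,536 4×4 masks and on
random 32×32 masks at both connectivities. Rounding is half-up where a
0–255 integer scale is produced; circularity is flagged at a relative
eigenvalue gap below 10⁻⁶; JPEG output is refused (lossy) while TIFF
and PNG round-trip 8-bit images losslessly.

## Known limitations

* Auto-segmentation assumes one dark object on a pale background; real
  slides with debris need provided masks (the canonical path).
* The ANOVA is a fixed-effects pooled analysis; experiment-replicate
  blocking and mixed models are out of scope.
* The tilt-alignment rule assumes roughly upright leaves; beyond ±45°
  the tip assignment is ambiguous and only flagged.
* Calibration assumes controls share the autofluorescence distribution
  of the stained samples' dead cells; batch effects between staining
  runs are not modeled.
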