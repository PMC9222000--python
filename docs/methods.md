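# Methods

`nucleomorph` re-implements, as an open and testable pipeline, a nuclear
morphometry workflow for discriminating low-grade (Gleason pattern ≤ 3)
from high-grade (pattern ≥ 4) prostate adenocarcinoma: a battery of 38
per-nucleus descriptors feeds a univariate ANOVA screen and a 7-variable
linear discriminant score with a ROC-chosen decision cutoff. Because no
image data from the original study are deposited, the package ships a
synthetic scene generator whose per-grade parameters follow the published
per-grade summary statistics, so every stage can be exercised and validated
end to end.

## Synthetic scenes

Each scene is an 8-bit RGB raster with an integer label mask and a
ground-truth table. Nuclei are star-convex: the boundary radius is
`r(θ) = R · (1 + ρ · f(θ))` with `f` a random sum of angular harmonics
(orders 2–13, 1/k amplitude decay, uniform phases) normalised to zero mean
and unit peak, so the maximal radial deviation is exactly `ρR`. Order-1
harmonics are excluded because they translate rather than roughen. Interiors
are filled with a spatially correlated Gaussian field (smoothing length
`texture_grain_px`, default 2 px) scaled per channel, plus Poisson-count
bright vesicle discs; the background is uniform light gray (230 ± 5),
darker-nuclei-on-light per haematoxylin convention. A one-pixel gap between
nuclei guarantees disjoint, single-component labels.

Per-grade defaults (base radius 3.36/3.63/3.72 ± 0.29/0.50/0.52 µm; R/G/B
means such as green 97.1/114.2/89.5) follow the published per-grade columns.
Boundary roughness (0.05/0.08/0.12) and texture grain have no published
counterpart; they are free generator knobs chosen once to keep grades
separable without dominating the size and intensity signals. Pixel
calibration defaults to 0.25 µm/px (unstated in the source; chosen so a
3.4 µm-radius nucleus spans ≈ 27 px at ×400), overridable everywhere.

What the generator deliberately does not model: gland/stromal architecture
(the grading system's actual substrate), stain physics, per-sample random
effects (nucleus parameters are i.i.d. within a cohort, so between-sample
variance is purely sampling noise and group separations are cleaner than in
tissue), and elliptical nucleus shapes (bases are perturbed circles with
radius set to the published *minimal* radius, so absolute mean areas run
~35–45 µm² rather than the published 54–71 µm²; orderings are preserved).
Passing end-to-end tests therefore demonstrate correctness of the pipeline
machinery and the generative design, not classifier performance on real
biopsies.

## Descriptor battery

Geometry is extracted per label: single 8-connected component enforced,
regions under 10 px rejected (not imputed), boundary traced as an ordered
Moore chain. Conventions with numeric consequences:

* **Perimeters.** `perimeter2` is the raw chain-code length (1 axial, √2
  diagonal), including binary hole boundaries. `perimeter3` is the
  *corrected* chain length — Vossepoel–Smeulders weights 0.948/1.340 plus a
  π term for the half-pixel offset between pixel centers and the region
  outline. The raw code overestimates smooth boundaries by ~5–6%
  (worst at 22.5° inclines); the corrected form is unbiased enough that a
  digital disk's isoperimetric roundness `perimeter3²/(4π·area)` lands in
  [1.00, 1.05], and the published battery itself carries both an
  uncorrected and a corrected perimeter at almost exactly this ratio.
  `perimeter_length` is half the corrected outline length (the battery's
  printed scale). The convex perimeter is the hull of boundary pixel
  centers plus the same π offset; collinear degenerate regions fall back to
  twice the point-span.
* **Radii, diameters, ferets.** Polar radii come from the boundary's
  per-degree maximum distance to the centroid plus 0.5 px (center-to-outline
  offset), giving 180 centroid diameters `r(θ)+r(θ+π)` on a 1° grid
  (configurable). Ferets are caliper extents of boundary points over the
  same 180 directions plus one pixel width, so an axis-aligned rectangle's
  feret equals its bounding-box side. `length` is the maximal feret,
  `width` the feret orthogonal to it.
* **Fractal dimension.** Box counting on the boundary chain over a
  quarter-octave size ladder 2, 3, 4, 6, 8, 11, … capped at
  min(64, bbox/4); per size the minimum count over four grid offsets
  approximates the covering infimum; the log N–log(1/s) slope is clipped to
  the planar-curve range [1, 2]. At least four sizes are required, else the
  value is flagged missing (NaN) — nuclei under ~12 px radius at default
  calibration. A smooth disk measures ≈ 1.00; roughened boundaries rise
  monotonically to ≈ 1.013 at ρ = 0.3 (averaged over 50 nuclei).
* **Intensity / optical density.** Luminance is the unweighted RGB mean;
  optical density is `256 − gray` (this exact convention, not the usual
  255, because the integrated-chromatin arithmetic depends on it);
  `iod = (256 − gray_mean) × area_µm²`.
* **Texture.** Heterogeneity: fraction of nucleus pixels deviating from the
  mean luminance by more than 10% of the mean. Clumpiness: fraction of
  those surviving one 3×3 majority erosion (≥ 5 deviant of 9), a cluster
  persistence in [0, 1]. Margination: mean OD of the peripheral band
  (pixels beyond ⅔ of the centroid-to-boundary distance in their direction)
  over 3× the whole-nucleus mean OD — exactly ⅓ for a radially uniform
  nucleus, matching the battery's ~0.33–0.35 scale. Texture needs ≥ 30 px.
  `holes` counts enclosed bright regions (luminance > mean + 1 SD) not
  touching the nuclear rim — vesicle-like objects, a true count. The
  vendor formulas behind margination, clumpiness and holes are not public;
  these definitions are fixed, documented contracts of this package and are
  tested against their own closed forms, not against the printed per-grade
  values.

All length outputs are `pixel measure × pixel_size_um` (µm), areas µm²,
shape measures dimensionless; doubling the calibration doubles lengths,
quadruples areas, and leaves dimensionless features untouched.

## Group statistics

Nuclei are averaged per biopsy sample (the unit of analysis; per-feature
missing values are excluded, never filled), then each feature is screened
with a one-way ANOVA across the three grade groups at α = 0.05. Features
passing the screen get the three pairwise comparisons as pooled-MSE t-tests
with Bonferroni correction ×3 — correction is per feature across the three
pairs, not across the battery, mirroring the original per-feature post-hoc
column. Unequal group sizes (24/20/16) use the standard unweighted ANOVA.
Whether the original analysis pooled nuclei or used sample means is not
stated; sample means are the default here (nuclei within a biopsy are not
independent) and the aggregation is a separate, skippable step. The
chromatin summary reproduces the published integer arithmetic — OD =
256 − round(green gray), quantity = OD × round(area) — alongside the exact
product.

## Discriminant scoring

The published 7-variable score (minimal radius, fractal dimension, min/max
gray, margination, green and blue gray) ships as a packaged JSON asset with
its printed coefficients, intercept 1331.50420234964 and cutoff −1.1134.
The source never states which side of the cutoff is high grade; evaluating
the printed formula at the published per-grade means gives −7.73 (grades
1–3), +9.77 (grade 4), +7.83 (grade 5), which fixes the orientation:
higher score ⇒ high grade. Ties at the cutoff classify high — favouring
sensitivity for the clinically risky class. Scoring refuses missing or
non-finite inputs rather than imputing.

Refitting uses forward stepwise linear discriminant analysis with the
Wilks-lambda partial-F criterion (entry p ≤ 0.05, removal p > 0.10,
configurable; the conventional defaults, unadjusted for the number of
candidates scanned — so with k pure-noise candidates the family-wise odds
of a nonempty model are ≈ 1−(1−α)^k, and an occasional noise variable can
join genuinely informative ones). Exact duplicates and collinear candidates
are skipped with a warning. Weights are scaled to unit pooled within-class
score variance with the class midpoint at zero. A logistic-regression Wald
variant (`method="logistic_wald"`) is available for sensitivity analysis;
the original description mixes the two vocabularies and the discriminant
reading is the default.

ROC thresholds sit at midpoints between adjacent distinct scores (±∞
flanks); a sample is called positive at score ≥ threshold. The AUC is the
trapezoid over (FPR, TPR) sorted lexicographically — equal to concordant
pair counting with ties at ½. The operating point maximises Youden's J,
ties broken toward higher specificity, then the larger threshold. Adding a
constant to all scores shifts the chosen cutoff by that constant and leaves
sensitivity/specificity unchanged.

## Problem sizes and reproducibility

The ANOVA calibration uses 200 replicate null screens of 54 features at
20 samples per group; stepwise recovery uses 100 replicates of 60 samples
with 2 informative + 8 noise candidates; the end-to-end experiment runs the
full study design (24/20/16 samples × 100 nuclei, 1024² scenes). One root
seed drives everything through spawned child streams; identical seeds give
byte-identical scenes and tables.

## Known limitations

* Absolute levels of heterogeneity/clumpiness/holes depend on definitions
  the original tool never published; only their contracts and closed-form
  cases are guaranteed here.
* The fractal-dimension estimator's dynamic range on ~30 px nuclei is
  narrow (≈ 1.00–1.02); it orders roughness correctly on average but is a
  weak single-nucleus discriminator at default calibration.
* The end-to-end AUC on synthetic cohorts (≈ 1.0) reflects the clean
  generative design, not expected performance on tissue; the original
  study's 97.2%/100% on its own 60 biopsies is not reproducible without
  its private data.
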