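# Methods

## Scope and data model

The package analyses digitized Nissl-stained cortical sections: one
greyscale image per section with a known μm/pixel calibration, an
operator-drawn layer label map (integer labels 1–6 for layers I–VI, 0
for background), and cohort metadata mapping each section to an animal
and an age class (calf, adult, old). The default cohort follows the
study design the statistics are built for: 4 calves, 4 adults and 3
old animals, two sections each, hence 22 images and image-level group
sizes 8/8/6.

Per segmented neuron the pipeline records eleven descriptors in three
domains:

* **size** — area (μm²), major and minor axis lengths of the
  moment-matched ellipse (μm), perimeter (μm, Crofton multi-direction
  estimator to limit rasterisation bias);
* **shape** — inverse aspect ratio (minor/major), extent
  (area / axis-aligned bounding box), eccentricity
  √(1 − (b/a)²), solidity (area / convex-hull area), and convex
  circularity;
* **density** — the number of other neurons whose centroids lie within
  50 and 100 μm of the neuron's centroid, computed within one section
  across all layers, centroid-to-centroid, without edge correction.

**Convex circularity** is not a standardised quantity; here it is
defined as 4π·A_hull / P_hull² of the convex hull — 1 for a disk,
smaller for elongated or angular hulls. Any consumer comparing against
another implementation should check this definition first.

Cells whose centroid falls on background are flagged and excluded from
analysis; cells touching the image border keep their centroid for the
neighbour counts of other cells but are excluded as focal records,
since their own morphometrics are truncated.

## Synthetic section generator

No histology ships with the package, so a generator emulates the
statistical structure the analysis assumes and provides exact per-cell
ground truth.

**Geometry.** Flat horizontal layer bands ordered I→VI from the pial
(top) edge; cortical curvature is not modelled because none of the
tested computations depend on it. The default column is 1.85 mm deep
(I 280, II 220, III 420, IV 110, V 440, VI 380 μm) in a 1.0 × 2.0 mm
field at 0.5 μm/px. Default densities (cells/mm²: 150, 900, 400, 120,
350, 300) make layer II the most cell-rich band and layer IV a thin
cell-poor line; they are free parameters of the generator, not claims
about any real cortex.

**Soma archetypes.** Four parametric outline families, each with a
mean equivalent diameter (lognormal, CV 0.15–0.18), an aspect ratio,
and an *irregularity* amplitude for a smooth random Fourier boundary
perturbation (orders 2–5):

| archetype | construction | diameter (μm) | aspect |
|---|---|---|---|
| round | circle | 12 | 1.0 |
| ellipsoid | ellipse | 13 | 0.62 |
| pyramidal | corner-rounded triangle (arc radius 0.35 × inradius), stretched | 15 | 0.78 |
| complex | 4–6-lobed radial polygon, lobe depth 0.26–0.34 | 19 | 0.90 |

The pyramidal template is elongated deliberately: an equilateral
triangle has isotropic second moments (inverse aspect ratio ≈ 1), so
without elongation it is indistinguishable from a round cell by
moment-based descriptors. The complex archetype's lobes are intrinsic
(present at irregularity 0); the irregularity channel adds variability
on top. Every sampled polygon is rescaled so its exact polygon area
equals π d²/4 for the drawn equivalent diameter d, which makes
Monte-Carlo checks of planted sizes exact in expectation.

**Group effects.** A `GroupEffect` scales mean equivalent diameter per
archetype (area therefore scales quadratically), shifts shape
parameters additively, and scales expected density per layer; an
optional layer restriction confines size/shape effects to a subset of
layers. All-identity effects define the global null used for
calibration.

**Rendering.** Dark somata (intensity ≈ 0.30 with per-cell staining
jitter, SD 0.05) on bright neuropil (≈ 0.78) with Gaussian texture
(SD 0.035) and a smooth random illumination field (amplitude 0.04),
quantised to 8 bits. Cell centres are placed by dart throwing with a
minimum separation of 0.62 × the summed diameters; a configurable
fraction of cells (default 0.10) is instead placed at 0.38–0.52 × the
summed diameters from a partner in the same layer, producing touching
or slightly overlapping pairs that exercise the watershed split and
supervised merge logic. Glia-scale distractors (3.5 μm disks,
≈ 9.6 μm² — below the 20 μm² neuron floor) are planted so the
minimum-area filter is exercised. Packing that would exceed 45% of a
band's area raises an explicit error rather than silently truncating.

**Truth-bypass mode.** `generate_cohort(render=False)` skips
rendering: polygons are sampled per layer, centres are placed
uniformly (overlap exclusion is irrelevant for feature statistics),
and all descriptors are computed analytically from the polygons
(shoelace area and second moments, vectorised convex hulls). This is
what makes 500-cohort calibration runs take minutes, and it is also an
independent oracle for the raster morphometry.

**What the generator does not emulate:** cortical curvature, staining
gradients along the section, anisotropic shrinkage, vasculature,
within-animal correlation between the two sections (sections are
independent given the group), and realistic background clutter beyond
Gaussian texture and glia dots. Passing tests therefore demonstrate
correctness of the algorithms and calibration of the statistics under
these idealisations — not segmentation performance on real histology.

## Segmentation

Six stages, all constants in `SegConfig`:

1. *Pre-processing* — greyscale conversion, Gaussian smoothing
   (σ = 1 px), 1st–99th percentile contrast stretch (monotone and
   invertible, preferred over histogram equalisation on sparse
   sections), then multiplicative neuropil standardisation: the
   neuropil summary is the median intensity outside a provisional
   triangle-threshold foreground, scaled to 0.75. Each step can be
   disabled independently.
2. *Foreground* — the operand (1 − image) + normalised Σ_σ σ²(∇²G_σ ∗
   image) is thresholded with the triangle method; morphology
   (opening, closing, one-pixel erosion to shave the halo the
   multi-scale map adds around blobs, hole filling) refines the mask.
   Default scales σ ∈ {3, 4, 6, 8, 11, 14} px span soma radii ≈ 2–10
   μm at 0.5 μm/px via the LoG scale-selection relation σ = r/√2.
3. *Markers* — a second multi-scale map takes the per-scale *maximum*
   instead of the sum (one dominant scale per soma); regional maxima
   surviving the extended h-maxima transform (h = 0.08 on the
   normalised map) and lying inside the foreground become watershed
   seeds.
4. *Watershed* — flooding relief 0.5 · gradient magnitude + 0.5 ·
   inverted multi-scale map, restricted to the foreground; one
   superpixel per marker.
5. *Supervised merging* — a random forest (100 trees, seeded) scores
   every adjacent superpixel pair on 21 rotation-invariant features
   (areas, perimeters, solidities and the solidity gained by merging,
   eccentricities, union convex circularity, shared-boundary fraction,
   normalised centroid distance, intensity means/SDs and interface
   contrast). Merges are applied greedily in descending score above
   0.5, recomputing affected pairs after each merge — the order is
   deterministic, ties break on pair id. Training pairs are labelled
   from synthetic ground truth (both superpixels mapping by majority
   overlap to the same true cell); the feature schema is versioned so
   real manual annotations can substitute.
6. *Post-processing* — hole filling and opening per object; removal of
   objects below the glia-exclusion floor (20 μm², configurable);
   Chan–Vese refinement on a padded local patch initialised at the
   mask (40 iterations, keeping the dark phase and the components
   overlapping the input; if the refined mask's IoU with the input
   drops below 0.5 the pre-refinement mask is kept and a warning
   logged); finally a second random forest rejects false-positive
   objects, trained on pre-area-filter candidates so glia-scale
   distractors appear as negatives.

On default synthetic sections the end-to-end object-level precision
and recall (IoU ≥ 0.5, Hungarian matching) both exceed 0.8 — with
trained classifiers typically ≥ 0.94 — and held-out pair-merge
accuracy is ≥ 0.9.

## Shape rules

An ordered decision list over shape descriptors only (size never
enters):

1. **complex** if solidity < 0.88 or convex circularity < 0.75;
2. **round** if invAR ≥ 0.85;
3. **pyramidal** if extent ≤ 0.66;
4. **ellipsoid** otherwise.

The thresholds are a reconstruction calibrated on the generator's
archetypes and shipped as a versioned config
(`synthetic-calibration-1`); `calibrate_rules` re-derives them by grid
search (macro-accuracy, deterministic smallest-threshold tie-break)
from any labelled record set. The extent threshold sits at 0.66 rather
than a lower value because a corner-rounded triangle that still
satisfies the convex-circularity floor of 0.75 (a sharp triangle has
convex circularity 0.605) necessarily has extent in 0.58–0.65 under
random orientation, while ellipses with aspect ≥ 0.6 stay above 0.68.
At irregularity 0 the rules agree with the planted archetype labels
for 100% of sampled cells; at default irregularity ≥ 99%.

## Statistics

**Pseudo-observations.** Cells within an image are spatially and
operationally dependent, so the independent unit is the image: for
each (image × layer × cell type) stratum with at least one cell, the
mean of each feature is one pseudo-observation. Strata with no cells
are *missing*, not zero. Pooled rows (`cell_type = "all"`) cover the
layer-wise analyses.

**Univariate test.** Pseudo-observations are independent but not
homoscedastic across groups, so the statistic is the Welch one-way F
for the three age classes. Inference is by random permutation of the
group labels over images (B = 999 by default, seed mandatory), with
the identity permutation included and ties counted:
p = (1 + #{b ≥ 1 : T_b ≥ T_obs}) / (B + 1). This convention guarantees
validity (p is stochastically ≥ uniform under the null) and a p-value
floor of 1/(B+1); with B = 19 and a strictly maximal observed
statistic it gives exactly 0.05. Permutations are at the image level,
following the pseudo-observation construction, even though two
sections share an animal; the generator's null (independent sections)
matches this scheme, and its calibration is verified by simulation.
Degenerate cases: a constant pooled sample gives statistic 0 and
p = 1; a permutation leaving some group with fewer than two
observations (possible in sparse strata) contributes +∞, which can
only inflate p (conservative); a hypothesis whose *observed* group
sizes are deficient is skipped with a diagnostic.

**Fisher combination.** All features of a hypothesis share one
synchronized set of shuffles. Within each permutation b, each
feature's partial p is its within-column proportion of
ties-or-larger statistics; the combining statistic is
T_b = −2 Σ_j log p_(j,b) and the combined p follows the same counting
convention. With a single feature this reduces exactly to the
univariate p; duplicating a feature leaves the combined p unchanged.

**Multiplicity.** Families follow the reporting structure: (a) domain
× layer over all cells, (b) domain × cell type × layer, (c) single
feature × cell type × layer. Within a family, the max-t correction is
taken across the six layers of each (measure × cell type) —
multiplicity six — in the single-step Westfall–Young form: each
hypothesis's T vector is rank-standardised to its per-permutation
p-scale (so hypotheses with different feature counts are comparable),
the per-permutation minimum over the family is recorded, and the
adjusted p of hypothesis h is the proportion of permutations whose
minimum is at least as extreme as h's observed value. Adjusted ≥ raw
holds by construction, and the adjustment is no more conservative than
Bonferroni on the same shuffles.

**Calibration (recomputed by `scripts/acceptance.py`).** Over 500
global-null truth-bypass cohorts (B = 200) the family-wise error of
the six layer-wise combined tests stays at or below 5% up to
Monte-Carlo error, and over 1000 null pseudo-observation datasets a
single combined test rejects at most ~5%. Power: a calf round-cell
area ×0.8 effect planted in layers I–III is recovered (max-t adjusted,
matched round-cell size family) in ≥ 2 of 3 planted layers in ≥ 80% of
replicates, with unplanted layers at chance rate.

## Problem sizes used in simulations

Calibration and power simulations run in truth-bypass mode on a
narrow tissue column — the full 1.85 mm six-layer depth with a 0.4 mm
(calibration) or 0.6 mm (power) wide strip — chosen so hundreds of
replicates of the full pseudo-observation → permutation → combination
→ max-t chain complete in minutes while every stratum keeps realistic
cell counts (layer IV, the sparsest band, still averages ~5 cells per
0.4 mm image). The statistical structure (group sizes, strata, feature
correlations) is unchanged by the strip width.

## Known limitations

* The segmentation constants are tuned for 0.5 μm/px thionine-like
  contrast; other magnifications require rescaling `log_sigmas` and
  `min_area`.
* Chan–Vese refinement on a local patch can capture fragments of a
  neighbouring soma inside the patch; the IoU guard bounds, but does
  not eliminate, this effect.
* The merge and false-positive classifiers are trained on synthetic
  truth; applying them to real sections without retraining on manual
  annotations transfers the generator's idealisations.
* Density counts ignore edge effects: cells near the field border have
  truncated neighbourhoods, biasing their counts downward equally
  across groups.
* Tissue shrinkage is not corrected; all lengths are in post-fixation
  section coordinates.
* The default permutation unit is the image, matching the
  pseudo-observation construction; this is exact for the generator's
  null (independent sections) but would be anticonservative if real
  sections from one animal were strongly correlated.  The stricter
  animal-level scheme (`run_family(..., unit="animal")`), in which the
  two sections of an animal inherit its permuted label as a block, is
  available for that case.
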