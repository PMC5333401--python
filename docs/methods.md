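# Methods

`phytoscreen` reimplements, at desk scale, the quantitative readouts of a
robotic seedling-phenotyping platform in which Arabidopsis seedlings grow
in gel-filled "Phytostrip" wells (strips of eight flat, 2 mm-deep,
22 mm-tall transparent vessels seated in a 96-well microtitre plate), are
dosed through the microtitre well below, and are photographed daily from
the side (roots, against matt black) and from above (shoots, against the
white plinth).  Because the package is developed without access to the
original camera data, a seeded simulator generates Phytostrip-style
images with exact per-pixel ground truth, and every stage of the analysis
is validated against that truth.

## Plate and filename model

A plate carries 12 strips of 8 wells; by convention the two end strips
(positions 1 and 12) are solvent controls, leaving 80 assay wells per
plate, and a 54-plate platform therefore runs up to 4320 simultaneous
assays.  Strip/well indices are 1-based (as in the filenames); pixel
coordinates are 0-based with the origin at the top-left and rows
increasing downward (the gel surface is row 0).  Image names follow
`[<experiment>_]Plate<id>_Strip<k>_<view>` with `view` in {Side, Top};
the experiment tag is everything before the first `Plate` token.  An
imaging-session count includes day 0 (the treatment day): a 7-day daily
time course has 8 sessions, which is how 10 treatments × 24 wells ×
2 views reach 3840 images.

## Dilution arithmetic

Compounds dispensed into the microtitre well equilibrate by diffusion
into the gel above.  The equilibrium ("theoretical final") concentration
is pure mass balance: `C_final = C_stock·V_aliquot / (V_aliquot +
V_medium + V_gel)`.  The default effective gel volume is 300 µl: wells
are filled with roughly 320 µl of molten gel, but the platform's own
standard numbers (a 25 µM well dose → 8.3 µM final; 1.5 µl DMSO →
0.33%) correspond to a 450 µl equilibrated volume over 150 µl of medium,
so 300 µl is the self-consistent default and the parameter is
user-settable.  With 320 µl the same dose evaluates to 8.0 µM; both
roundings appear in practice.  Internal values are never rounded;
reporting helpers round half-up to the printed precision (1 d.p. for
concentrations, 2 d.p. for percentages, 1 d.p. for hit rates — 70/800 =
8.75 → 8.8%).

## Synthetic imaging

**Geometry.** A side-view well is 440 × 120 px at 0.05 mm/px (22 mm
depth).  The real macro optics resolve individual ~10 µm root hairs
(≈0.02 mm/px); 0.05 mm/px keeps the thinnest structures several pixels
long while staying cheap, and root hairs are drawn 1.2 px wide — wider
than optical reality — so that, as in the real photographs, they remain
visible structures carrying mass.

**Growth model.** A discrete-step heading random walk (step = 1 px).
Each step the heading (measured from the downward vertical) is pulled
toward vertical by the `gravitropism` weight in [0, 1] and perturbed by
a Gaussian of s.d. `tortuosity` degrees; the walk reflects off the side
walls and truncates at the well bottom.  Laterals arise as a Poisson
process along the primary (default 0.02/px = 4 per cm), emerge at
~20° from horizontal after a 2-day maturation delay, and elongate at
their own rate with weak gravitropism; root hairs are straight,
near-perpendicular emergences (default 0.3/px = 6 per mm, 8 px =
0.4 mm long, 15° angular spread) placed on the parent's edge outside
the elongation zone.  Defaults describe a healthy 7-day-old seedling
(2.2 mm/day primary) with two plants per well, matching the screen's
sowing density.  Seven presets reproduce the qualitative phenotype
classes a chemical screen reports: `control`, `no_laterals`,
`short_primary`, `long_hairs`, `no_hairs`, `agravitropic_wavy`,
`dense_laterals`.

**Rendering and ground truth.** Every polyline leg is rasterised as a
butt-capped stroke on a 3× supersampled lattice, half-open along both
axes, so strokes tile without double counting and an axis-aligned bar of
length L and width w covers exactly L·w pixel units.  The noise-free
per-pixel coverage (union over structures, values in [0, 1]) is the
ground-truth probability map; the truth orientation is the
coverage-weighted mean of the folded tangent angles of the samples in
the pixel, a continuous field in [0°, 90°] measured from horizontal
(orientation is undirected, so a segment and its mirror image fold to
the same angle).  Where structures of different orientation genuinely
overlap within one pixel no single angle is "the" truth; the mean
degrades gracefully rather than switching on sub-resolution detail
(a winner-take-all dominant-structure definition was evaluated and
rejected for exactly that discontinuity).  Blur (σ = 0.6 px, reflect
boundaries, mass-preserving) and additive Gaussian noise (σ = 0.02)
are applied to the image only, never to the truth layers.  Overhead
views render the rosette as hard-edged overlapping ellipses of a given
HSV hue on white; the shoot mask is their union.  All randomness flows
through explicit integer seeds; there is no global random state.

What the simulator does **not** emulate: gel optics (refraction,
reflections, condensation), illumination gradients, germination-timing
variation, seed coats and agar debris, multi-seedling occlusion in
depth, and camera artefacts (vignetting, JPEG compression).  Passing
tests therefore demonstrate the correctness and internal consistency of
the analysis chain on idealised scenes, not its robustness to every
nuisance of real captures.

## Root-trait extraction

**Likelihood map.** Pixels get a root likelihood in [0, 1] rather than a
hard label.  Background level and noise are estimated from the lower
intensity tail (10th/25th percentiles) because roots are strictly
brighter than the matt-black card and can cover enough of a crowded well
to contaminate a median.  Candidate pixels must clear the noise floor
and carry a multiscale Sato ridge response; speckles under 4 px are
dropped; the likelihood is background-subtracted intensity normalised by
the estimated stroke brightness (99th percentile of core pixels),
clipped to [0, 1], restricted to a 3 px dilation of the detected
structures so the blur skirt keeps its mass.  Because rendering blur
redistributes intensity without destroying it, the map's sum tracks true
stroke coverage (≤0.2% error on noise-free renders across all presets).

**Orientation.** Root material is two very different populations, and no
single local operator serves both, so the likelihood map is decomposed
by local width (distance transform of the thresholded map):

* the *backbone* (primary and laterals, wider than 2 px) takes
  per-pixel structure-tensor orientations.  The tensor is built from
  Gaussian-derivative gradients (σ = 0.7 px, window 1.4 px): a 2-tap
  difference gradient is measurably anisotropic, biasing oblique
  orientations ~2° toward the pixel axes — material when binning into
  22.5° classes — and the eigenvector comes from the half-angle formula
  `0.5·atan2(2A_rc, A_rr − A_cc)`, which stays stable where the
  off-diagonal term cancels (naïve eigenvector selection flips 0°↔90°
  on exact centrelines);
* each remaining thin connected component is classified by its
  straightness (rms off-axis spread ≤ 1 px): straight strokes — root
  hairs — get one axis from a likelihood-weighted PCA of their pixels,
  and their footprint is extended 2.5 px along that axis over the
  backbone so a hair's base keeps the hair's angle instead of the
  parent's; curved or tangled thin material gets per-pixel local PCA
  restricted to thin-structure pixels, with end-claims into the
  backbone at junctions.

Blur-skirt pixels inherit the angle of the nearest assigned structure.
A pixel's orientation is *valid* when its likelihood is ≥ 0.02 and an
angle was assigned; invalid mass still counts toward root mass but no
orientation bin.

**Traits.** The well is split into four equal-height horizontal
quadrants Q0 (top) … Q3 (bottom); remainder rows go to the topmost bands
so the partition is bit-reproducible.  Orientation bins are [0°, 22.5°),
[22.5°, 45°), [45°, 67.5°), [67.5°, 90°].  `root_mass` is the sum of
likelihoods; `q[i][j]` sums likelihood over valid pixels in band i and
bin j; `Q0-horizontal` = q[0][0] (hairs and laterals) and `Q3-vertical`
= q[3][3] (primary extension) are aliases, not separate computations.
The identity `Σq + invalid_mass = root_mass` holds exactly because all
three are accumulated from the same partition.

**Accuracy against ground truth.**  On 20 noise-free wells per preset,
root mass agrees with truth to ≤0.2% and isolated straight bars at
0°/45°/90° are recovered within 0.6°.  Individual quadrant × bin entries
carrying ≥1% of a preset's mass agree within ~8% for sparse scenes
(`short_primary`) but only within 10–29% for crowded ones
(`dense_laterals`, `no_hairs`, `long_hairs`): at junctions and overlaps
the truth assigns whole-pixel mass to one structure while the image
holds a genuine mixture, and that attribution is not observable at the
sensor.  The accompanying acceptance tests assert the ±10% bin-level
contract as stated and are expected to fail for the crowded presets;
the headline traits and all well-level masses are unaffected.

## Shoot traits

Shoot material in an overhead image is simply the coloured part: pixels
with HSV saturation ≥ 0.15 (white plinth, grey shadows and black borders
are all unsaturated) and value ≥ 0.05 (near-black pixels have no
meaningful hue).  `leaf_area` is the mask pixel count — the projected
(union) rosette area, which understates true leaf area once leaves
overlap; no 3-D correction is attempted.  `leaf_hue` maps each mask
pixel's hue to a bounded red(0°)–green(120°) axis — hues in (120°, 300°]
clamp to 120 and beyond 300° to 0, since seedling shoots occupy the
red–yellow–green sector — and averages over the mask.  Hue is a ratio of
chromatic components, hence invariant under uniform brightness scaling.
An empty mask yields a flagged undefined hue, never a number.

## Time-course aggregation and flagging

Per-well records join to a plate map (well-level, or strip-level when
the map carries no `well_index`), then mean, SE and n are reported per
treatment × day × trait.  SE uses the sample (n−1) standard deviation
over √n; n = 1 leaves SE undefined; missing wells are dropped, never
imputed.  `control_deviation_flags` is deliberately simple screen
plumbing: flag a treatment on a trait when its mean is more than
`z_threshold` (default 3) control standard errors from the control mean,
requiring the same-direction deviation in every replicate when replicate
structure is supplied.  No multiple-testing correction by default (a
primary screen is hypothesis-generating); `alpha` switches to a
two-sided Bonferroni-adjusted normal quantile.

## Numerical and design choices

* Reported trait tables are sorted and written with fixed float
  formatting, so simulate → analyze → aggregate is byte-reproducible for
  a fixed seed.
* Each imaging session re-grows a well from the same seed at the
  session's age; ontogeny is approximated per session, not tracked
  between sessions.
* Overlapping crop boxes warn but run; boxes outside the image raise.
* Degenerate inputs: an all-background or all-saturated image yields a
  zero likelihood map; wells with no detected structure produce zero
  traits, not errors; fewer than 4 image rows cannot form quadrants and
  raise.
* Problem sizes in the test-suite and acceptance script (8–24 wells per
  condition, 5-dose series, single-plate pipelines) were chosen to give
  stable means and clear separations at desk scale.

## Known limitations

* Bin-level orientation traits in crowded scenes carry the systematic
  junction-attribution error quantified above; comparisons *between*
  treatments (the platform's actual use) are unaffected because the
  bias is shared.
* The background model assumes roots brighter than background; the
  GUS-staining use case (dark-blue precipitate on white) is ingested but
  not specially handled.
* The hue axis is bounded red–green; anthocyanin-purple shoots would
  clamp rather than extrapolate.
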