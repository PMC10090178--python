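# Methods

## Overview

`hippocount` estimates pyramidal-neuron numbers in histology partitions
two ways — a 2D segmentation-plus-filtering pipeline and a 3D
optical-fractionator simulation — and validates both against synthetic
tissue whose ground truth is exact by construction. This note documents
the generative model, the procedures, their parameters, the numerical
conventions, and what the synthetic results do and do not say about real
slides.

## Synthetic tissue model

A slab is a `width × height × thickness` volume (defaults 1000 µm ×
1000 µm × 20.39 µm, the latter chosen as a typical mounted thickness of
a 50 µm-cut, dehydrated section). Four object classes are placed by
homogeneous Poisson processes with per-class planar densities
(cells/mm²):

| class     | default density | diameter model                    | role |
|-----------|-----------------|-----------------------------------|------|
| pyramidal | 350             | lognormal, median 18 µm, σln 0.10 | the countable population |
| glial     | 100             | lognormal, median 7 µm, σln 0.15  | false positive: small dark cells |
| profile   | 60              | neuron diameter × U(0.25, 0.50)   | false positive: somata mostly cut away into the adjacent section |
| debris    | 60              | U(3, 8) µm                        | false positive: faint extracellular blobs |

Defaults were chosen once to produce a touching-but-resolvable pyramidal
layer (mean nearest-neighbour spacing ≈ 22 µm against an 18 µm soma)
with a realistic admixture of confounders; a 750 µm vignette then
contains ≈ 200 in-plane neurons. All densities, distributions, and the
overlap fraction are configurable in `SlabSpec`.

**Depth sampling is nucleolus-first.** Each cell's nucleolus is uniform
over `[0, thickness]`; the soma center sits at the nucleolus plus a
uniform draw inside a concentric ball of half the somal radius (so the
nucleolus always lies inside the soma, and centers may protrude slightly
past the cut faces, as real somata do). This makes the countable points
uniform in depth, which is the property disector counting relies on.

**Overlaps.** A fraction (default 5%) of pyramidal cells is re-placed as
touching pairs with center distance below the mean somal radius,
emulating overlapping neurons that the 2D pipeline deliberately counts
as one.

**Rendering.** Somata become filled ellipses on a light background
(205 gray): the aspect ratio is drawn from U[1.0, 1.6] and split
area-preservingly between the axes, so the equivalent-circle diameter of
the drawn region equals the somal diameter (18 µm ⇒ 24 px at
0.75 µm/px). Intensities per class: neurons and profiles U(60, 140),
glia U(100, 160), debris U(180, 200) — neurons at least 30 gray levels
darker than background, debris close to it, so the intensity filter has
something to do. Cells whose center lies outside the focal depth
interval are drawn with the spherical cross-section at the nearest
interval edge and flagged out-of-plane; profile-class cells are drawn at
their reduced fraction regardless. The explicit fraction — rather than
pure clipping geometry — is a deliberate simplification: geometric caps
concentrate near full size, whereas the profile population is meant to
be distinctly smaller than in-plane neurons so that the size-based
filter is a meaningful test. Additive Gaussian noise (σ = 4) is applied
last. Labels are drawn debris → glia → profiles → neurons; instances
fully overdrawn are dropped and the rest relabeled contiguously, so
every rendered cell owns exactly one label.

What the generator does **not** emulate: optics (no point-spread
function or defocus blur), staining texture within somata, dendritic
processes, anisotropic shrinkage, and spatially structured cell
arrangements (the pyramidal layer's banding). Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under controlled conditions, not segmentation performance on real
slides.

## Preprocessing

Order: 8-bit conversion (Rec.601 luma for RGB; linear min–max rescale
for 16-bit) → bounding-box crop with polygon rasterization → inversion
`v ↦ 255 − v` inside the mask → percentile auto-contrast (default 0.35%
saturated per side, the common default of interactive histology
software). Whether inversion precedes or follows contrast adjustment is
a convention; the chosen order is recorded in each partition's
provenance. Outside-polygon pixels are 0 on the inverted image and are
excluded from every downstream statistic.

## Segmentation

The `classical` backend: Gaussian smoothing (σ = diameter/8), Otsu
threshold over the valid mask, hole filling, removal of specks below 5%
of the expected soma cross-section, Euclidean distance transform, peak
seeds with minimum separation diameter/2, and marker-based watershed.
It is fully deterministic. "Flexible" diameter (`diameter_px=None`) is
estimated as twice the median distance-transform peak height. The
`model` backend calls the pretrained CellPose network when the optional
package is installed; its thresholds are pass-through configuration
recorded in provenance. Both backends return contiguously relabeled
instance maps confined to the valid mask, so filtering is
backend-agnostic.

Diameter piloting segments a set of partitions at candidate diameters
(flexible, 23, 24, 26, 27 px by default) and, when ground-truth label
maps exist, ranks them by detection F1 under one-to-one Hungarian
matching at IoU ≥ 0.5.

## False-positive filtering

Per partition, in order:

1. **Intensity**: threshold = mean inverted gray over the valid mask;
   objects with mean inverted gray strictly below it are removed.
2. **Diameter**: over the intensity survivors, µ and sample SD s (n−1)
   of the ellipse minor-axis diameter in µm; objects strictly below
   µ − k·s are removed (default k = 0.75; piloted set 1.0 / 0.75 / 0.5).
   No upper threshold — overlapping neurons count as one.
3. **Edge** (vignette mode only): objects touching the image border are
   removed, matching the rater protocol.

Computing the diameter statistics after the intensity filter keeps
background artifacts from corrupting µ and s. Boundary cases use strict
inequalities. Re-filtering re-estimates thresholds by definition; the
testable idempotence contract is that re-running the diameter filter on
its own kept set under *frozen* (first-pass) statistics removes nothing.
The ellipse fit uses central second moments with population
normalization (full axis = 4·√eigenvalue), which is exact for uniform
ellipses; degenerate pixel sets get minor axis 1 px.

Filter quality is scored against the synthetic class ledger with a
center-point rule: a planted cell is "kept" when its center pixel lies
inside a kept instance. This credits merged overlapping neurons —
which the method keeps by design — so sensitivity isolates what the
*filter* removed from what the segmentation failed to split. At default
conditions the measured planted-neuron sensitivity is ≈ 0.99 and
non-neuron rejection ≈ 0.84.

## Optical fractionator

Probe geometry defaults: 50 µm × 50 µm frames, 10 µm disector, 3 µm
guard zones, ssf = 1, ~10 frames per ROI (spacing = √(area/target)) or an
explicit grid spacing. One uniform random offset in `[0, s)²` shifts the
whole grid per replicate; a frame hangs off every node whose rectangle
intersects the ROI. A nucleolus is counted when it is inside the
half-open frame (x ∈ (x0, x0+w], y ∈ [y0, y0+h)) — the point-particle
reduction of the unbiased counting frame's left+bottom exclusion lines —
inside the ROI, and at depth z ∈ [guard, guard + h). Placing frames by
rectangle intersection rather than node membership matters at ROI
edges: it gives every ROI point a sampling probability of exactly
asf·h/t, making the estimator unbiased with no boundary strip, and
makes exhaustive tiling (spacing = frame size, full-thickness disector,
no guards) recover the true count exactly on every replicate — both
properties are asserted in the tests. Thickness is measured at each
frame center (a configurable smooth field exercises this; default
constant 20.39 µm), and t̄ is Q-weighted by default with an
arithmetic-mean option.

## Method comparison

Dice uses binarized masks; both-empty is defined as 1 (vacuous
agreement). The Dice group comparison defaults to Welch's
independent-samples t-test with the paired form behind a flag, and
reports which was used. The method-statistics report contains
Shapiro–Wilk screens, the paired Wilcoxon test (all-zero differences
reported as degenerate with p = 1), Spearman correlations on subregion
means and on individual partitions, two Kruskal–Wallis tests by
subregion, Dunn's pairwise post-hocs (tie-corrected z) under Holm
correction, and quartile/mean/SD/SEM/95% CI descriptives. All tests are
two-sided at α = 0.05.

## Study sizes and numerical choices

- The end-to-end validation uses 30 partitions of 600 µm × 600 µm with
  pyramidal density log-spaced over 200–2000/mm² (a 10-fold span) and
  target_frames = 25 for the fractionator: the small synthetic ROIs get
  the same per-frame counting statistics as large real subregions
  sampled with ~10 frames. Observed Spearman r between the pipeline
  estimate and the simulated stereology count is ≈ 0.93–0.95.
- Unbiasedness is checked on a ~1000-neuron slab over 200 independent
  offsets (Monte-Carlo SE of the replicate mean ≈ 2.5%).
- All RNG flows through `numpy.random.default_rng` seeds carried in the
  specs/params; identical configuration and seed reproduce every output
  byte-for-byte.
- Labels are int32 internally, written as uint16 TIFF when they fit.

## Known limitations

- The classical backend under-segments dense clusters (merged instances),
  so absolute 2D estimates drop below truth as density grows; rank order
  across partitions is preserved, which is the quantity the comparison
  statistics test.
- The 2D estimate and the 3D fractionator target different quantities
  (visible in-plane somata vs nucleoli in the volume); the package
  compares them by correlation, not identity.
- Dunn's test uses the normal approximation; very small groups (< 5)
  give coarse p-values.
- The `model` backend is untested in this repository's suite (the
  network weights are an optional dependency); its contract is enforced
  only at the InstanceMap level.
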