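# Methods

## The quantity being computed

After transection and end-to-end repair of a peripheral nerve, the axon
segments distal to the repair site fragment into chains of ovoid debris
(Wallerian degeneration) and are later replaced by thin regenerating
axons. In cleared, immunostained nerve volumes this history is legible in
the *shape* of the connected fluorescent structures: intact and
regenerating axons are long, highly elongated segments, debris is short
and ovoid.

The pipeline quantifies this with a **normalized length score** per region
of interest (ROI):

1. An ROI of 200 × 200 × 24 µm³ is cut from the volume and collapsed to
   2-D by summing 13 z-slices at 2 µm intervals.
2. The projected image is binarized (Otsu by default; a fixed threshold is
   available for exact replication of a chosen cutoff). Foreground is
   strictly above threshold.
3. Connected components (8-connectivity by default) are measured:
   eccentricity and major-axis length of the ellipse with matching second
   central moments, filled area (interior holes filled with the standard
   full-connectivity hole definition), raw pixel count, and additionally
   the maximum Feret diameter, reported per segment because the classical
   "major axis" could also be read as a Feret length.
4. A segment is **long** iff, strictly, eccentricity > 0.99 *and* major
   axis > 200 px *and* filled area > 2000 px; otherwise **short**.
   Segments touching ROI borders are kept — long axons necessarily touch
   both borders of a 200 µm field.
5. score = (pixels in long segments) / (pixels in all segments), using raw
   (unfilled) pixel counts in both numerator and denominator. 32 ROIs are
   sampled per volume (uniformly, with replacement; origins logged) and
   the timepoint is summarized by their mean ± sd.

A healthy nerve scores 1; the score falls through the first post-operative
week, reaches a minimum around day 9, and recovers toward 0.4–0.5 by day
12 as thin regenerating axons repopulate the field.

The pixel-unit thresholds presuppose a pixel size. The default lateral
spacing is 200/512 µm ≈ 0.39 µm, so that one ROI is exactly 512 px wide
and a field-spanning axon has a moments-ellipse major axis of
≈ 1.155 × 512 ≈ 591 px, comfortably above the 200 px criterion; the
spacing is configurable and the physical meaning of the thresholds scales
with it.

## Synthetic nerve volumes

No public image data accompany the analysis protocol, so every stage is
validated on synthetic volumes with planted per-voxel ground truth
(background / long axon / fragment).

**Geometry.** The default scene is a thin longitudinal slab of nerve —
x = 700 µm along the nerve axis, y = 200 µm, z = 24 µm, i.e. exactly one
ROI wide and one ROI thick — holding 12 axon tracks. Tracks run the full
x extent, undulate gently in y (amplitude ≤ 2 µm, wavelength ≈ 250 µm,
within the ≤ 2-radius bound), hold constant z, and are stratified in y
with a minimum clearance so neighbouring structures never merge in
projection and no track is clipped by the slab borders. Because the slab
cross-section equals the ROI cross-section, every track is wholly
contained in every ROI and ROI randomness lives along x. This is a
deliberate idealisation: an ROI border that slices a tube lengthwise
produces a strip whose pixel count falls arbitrarily close to the
filled-area threshold, i.e. a segment whose long/short label is a
coin-flip of geometry rather than biology. Real 200 µm fields contain
such strips; the simulator excludes them so that ground truth is exact
and a baseline field scores exactly 1. Consequences for interpretation
are listed under *Limitations*.

**Axons and debris.** Intact axons are tubes of radius 3.5 µm (day-12
regenerating axons: 3.0 µm, reflecting the consistently thinner calibre of
regrowth). Degenerated tracks carry chains of prolate ellipsoidal ovoids
(aspect ratio 1.5–3, i.e. lengths 3–6 lateral radii) separated by gaps
drawn from 4–10 µm. Intensity falls off radially as a sharp-edged
super-Gaussian, `exp(-2 (d/r)^4)`: nearly flat inside the labelled radius,
e⁻² at the boundary. The quartic edge makes the thresholded width of a
structure insensitive to the exact threshold level (a ±30% change in the
Otsu threshold moves the measured width by only a few percent), which
keeps the score stable under the intensity inhomogeneities below.

**Score calibration.** The planted long fraction is defined over labelled
*voxels*, while the score counts projected *pixels*. A tube of radius r
carries π r² labelled volume per unit length against a thresholded
projected width ≈ 2 k r (k the threshold width factor); an ovoid chain
carries (4/3) π a b² volume against ≈ π (k a)(k b) projected area per
fragment. Equal projected-pixel weight per labelled voxel across the two
classes therefore requires b ≈ 0.85 r/k. Two defaults implement this:
debris lateral radius = 0.84 × the stage's intact-axon radius, and debris
rendered brighter by the inverse radius ratio so tube and ovoid
*projected* peaks match (a z sum-projection integrates a structure over
its axial extent; without the correction thin debris is systematically
dimmer than axons and a shared threshold trims proportionally more of its
area — condensed debris also stains densely in real tissue). With both in
place the measured mean score tracks the planted voxel fraction to within
±0.01 across the stage presets, against the ±0.05 recovery tolerance the
tests assert.

**Planted-fraction targeting.** Whole tracks are assigned intact or
fragmented; an analytic estimate picks the intact count, and the residual
is closed by scaling all inter-fragment gaps by a common factor (clamped
to [0.4, 2.5]), re-rendering and re-measuring up to four times until the
label-derived fraction is within ±0.02 of the target. Unreachable targets
raise an error stating the achievable range. The stage presets plant
1.0 / 0.7 / 0.3 / 0.15 / 0.45 for baseline / d3 / d6 / d9 / d12. The d9
preset overrides the debris radius to the parent-axon calibre (3.5 µm):
with default thinner debris, a single intact track already exceeds the
planted minimum of 0.15 against the maximal debris mass the slab can
hold, so full-calibre fresh debris — plausible at the height of
degeneration — keeps the minimum reachable by whole-track allocation (at
the cost of a ≈ +0.03 overshoot in the measured d9 score, immaterial to
the time-course ordering).

**Optics and noise.** In order: optional radial staining decay
(`exp(-depth-from-surface / c)` toward the nerve core, emulating limited
antibody penetration; disabled in the stage presets because the default
slab sits deep inside a 500 µm-radius nerve), anisotropic Gaussian PSF
(lateral σ 0.5 µm, axial 3×, matching the axial elongation of confocal
stacks), exponential depth attenuation (length constant 150 µm),
Poisson–Gaussian noise (gain 1, read sd 5 against a peak of 3000), clip
at zero, quantise to 16-bit. Labels are never blurred. Everything is
driven by one `numpy` generator seeded from the scene seed;
generation is bit-reproducible.

## Virtual reslicing and profiles

The nerve axis is assumed aligned to a volume axis (the caller states
which); sections orthogonal to it reproduce stored voxel planes exactly at
on-grid positions under nearest interpolation, and anisotropic voxel
spacing is carried in the section rather than resampled. Depth/lateral
profiles are plain means over caller-supplied rectangles; the
depth-attenuation constant is recovered by log-linear least squares on the
positive profile samples (exact on noise-free uniform content, within a
few percent under the default noise).

## Sciatic functional index

SFI = −38.3·(EPL−NPL)/NPL + 109.5·(ETS−NTS)/NTS + 13.3·(EIT−NIT)/NIT − 8.8,
per print, averaged over ≥ 3 consecutive prints (fewer is tolerated with a
warning). The coefficients are the Bain–Mackinnon–Hunter values and are
config-overridable. Identical prints give exactly −8.8 — the formula's
constant term — although the index is conventionally *described* as 0 for
a healthy nerve; the raw formula value is reported and no re-zeroing is
applied unless the caller passes an explicit offset. Percent recovery
anchors −100 (complete transection) at zero function:
100·(SFI+100)/(SFI_baseline+100).

The print generator interpolates injured-side geometry linearly between a
complete-transection preset and the normal side (print length 30 mm, toe
spread 18 mm, intermediary toe spread 9 mm — representative adult-rat
values). The transection preset fixes a +30% print-length and −65%
toe-spread deficit and *solves* the intermediary deficit from the formula
so that recovery fraction 0 evaluates to exactly −100; because the formula
is linear, recovery fraction f maps to SFI = −100 + 91.2 f and percent
recovery equals 100 f without approximation. Gaussian measurement noise
(default 0 in the API, 0.3–0.5 mm in the examples) perturbs each print.

## Numerical choices

- Projections are held in float64 and never rescaled before binarization;
  binarization uses strict `>`.
- Thresholds are strict inequalities; a segment exactly at any threshold
  is short (regression-tested).
- z is the first array axis; coordinates are 0-based; ROI z spans are
  plane-inclusive (13 planes at 2 µm span 24 µm); lateral ROI sizes are
  pixel counts (`round(edge / spacing)`).
- Connected components on masks ≤ 64 px are cross-checked against
  brute-force moment sums and flood-fill hole filling at 1e-9.
- ROI sampling with replacement; a region admitting exactly one position
  returns identical copies with a warning rather than failing.
- Empty masks yield empty feature lists; an ROI with no foreground gets a
  flagged invalid score and is excluded from summaries with a warning.

## What the synthetic tests do and do not show

The simulator demonstrates that the pipeline recovers planted composition
under realistic intensity inhomogeneity, blur and shot noise, and that the
published anchor values (baseline 1, day-12 0.4–0.5, the non-monotone
time course) follow from the stated geometry. It does **not** emulate:
border-clipped axons at ROI edges (see above), fascicle-level anatomy or
multi-bundle cross-sections, axons leaving the imaging plane, mosaic
stitching seams, staining artefacts, or anatomically realistic axon
densities (12 tracks per 200 µm field vs hundreds in a real nerve).
Passing tests therefore establish correctness of the measurement given
the model, not field performance on animal data.

## Problem sizes

Default volumes are 13 × 512 × 1792 voxels (≈ 12 M, uint16); one stage
generates in ≈ 10–15 s and scores 32 ROIs in ≈ 3 s on one CPU. The
five-stage time course runs in under two minutes.
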