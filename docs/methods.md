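# Methods

`mammometry` measures breast asymmetry from a single frontal
photograph.  Its inputs are a 30-point landmark annotation (manually
placed or produced by the built-in detector) and at least one physical
anchor distance in centimeters; its outputs are four clinical
distances per side and seven asymmetry indices, in pixel, centimeter
and dimensionless form.  This note documents the model, the
conventions adopted where the problem is under-determined, the
synthetic data that stands in for clinical photographs, and the known
limitations.

## Landmark schema and coordinate conventions

The schema has exactly 30 roles: sternal notch, umbilicus, two
nipples, and a 13-point "footprint" contour per breast (the outline of
the breast's extent on the chest wall).  Coordinates are continuous
pixels, origin at the top-left pixel center, x rightward, y downward;
"inferior" therefore means larger y on an upright photograph.  `L`/`R`
are the patient's sides, so the patient-right breast sits on the
viewer's left.  Footprint ordinal 1 is the most medial-superior
station; ordinals proceed laterally along the superior border and
return medially along the inferior border.  A valid set has every role
exactly once, simple (non-self-intersecting) footprint polygons, and
each nipple inside or on its own footprint.

All measurements are taken in a midline frame anchored at the sternal
notch: the midline is the line through sternal notch and umbilicus
(the only two midline landmarks available), u is the signed
perpendicular distance from it (positive patient-left), v the signed
distance along it (positive inferior).  Because the frame is built
from landmarks, every quantity is invariant to how the patient happens
to be rotated or translated in the camera frame; the test suite
asserts this to 1e-9.

## Preprocessing

Intake standardization is: letterbox to a target aspect ratio
(default 3:4) by symmetric zero padding, isotropic bilinear resize so
the long side is 1024 px, then per-image linear min-max mapping to
8-bit (a constant image maps to zeros, the one deterministic choice
that avoids 0/0).  Padding is split into whole pixels (top/left gets
the smaller half) and the recorded affine transform is that exact
integer translation, so landmark coordinates move analytically with
the pixels and no source pixel is ever resampled by the letterbox.
Stretching is never used: anisotropic scaling would corrupt the
distance ratios that centimeter calibration depends on.

## Calibration and clinical distances

A photograph carries no physical scale, so the user supplies one of
three anchor distances: sternal notch to right nipple, sternal notch
to left nipple, or nipple to nipple.  The scale is cm_per_px =
anchor_cm / anchor_px.  When several anchors are supplied a fixed
precedence (right anchor first) selects one; anchors are never
averaged, mirroring the usual validation protocol in which the
right-sided distance is the one recorded.

Clinical distances per side: SN-N (sternal notch to nipple,
straight-line), N-S (nipple to sternum, taken as the perpendicular
distance to the midline — the quantity a frontal photo can actually
offer), N-IMF (nipple to the inferior-most footprint point along the
midline direction, the 2-D proxy for the nipple-to-inframammary-fold
tape measurement), and BBW (breast base width, footprint extent
perpendicular to the midline).  The N-IMF proxy deliberately measures
only the projected chord: on a ptotic breast the tape runs over the
curved lower pole and is longer, so the proxy under-reads.  That bias
is a property of frontal photogrammetry, not a defect of the
implementation, and the agreement module exists to quantify it.

## Asymmetry indices

With nipples at (uL, vL), (uR, vR) and footprints FL, FR
(FR' = FR mirrored across the midline):

| index | formula | meaning |
|---|---|---|
| BRA | sqrt((&#124;uL&#124;-&#124;uR&#124;)^2 + (vL-vR)^2) | breast retraction assessment |
| UNR | &#124;vL - vR&#124; | upward nipple retraction |
| LBC | &#124;arcL - arcR&#124; | lower breast contour difference |
| BCE | &#124;(vlowL-vL) - (vlowR-vR)&#124; | nipple-to-inferior-contour drop difference |
| BCD | &#124;perim FL - perim FR&#124; | contour (perimeter) difference |
| BAD | &#124;area FL - area FR&#124; | area difference |
| BOD | area FL + area FR' - 2 area(FL∩FR') | overlap (symmetric) difference |

The index names are established in the photometric literature but no
single canonical formula set exists; the definitions above are the
classical ones and live in one module so an alternate convention can
be swapped in one place.  Two conventions deserve explicit mention:

* The *inferior border* used by LBC is fixed as ordinal stations 7-13
  of the footprint ring (the lateral-to-medial inferior sweep implied
  by the ordering convention).  An earlier draft selected endpoints by
  coordinate comparison (medial-most / lateral-most vertex); that
  selection is discontinuous under small coordinate noise — one
  sub-pixel jitter can add or remove a whole polygon segment from the
  arc — whereas the ordinal convention makes LBC a continuous function
  of the vertex positions.
* Footprint polygons are the piecewise-linear closure of the 13
  ordered points.  No spline smoothing is applied: smoothing changes
  areas in ways that depend on the smoothing parameters, and
  reproducibility is worth more than cosmetic smoothness.

Dimensionless variants divide lengths by the mean of the two SN-nipple
pixel distances and areas by the larger footprint area, giving
scale-free fractions usable when no physical anchor is available.
Without a calibration the dimensional fields are explicitly flagged
unavailable rather than silently zero.

Polygon area and perimeter use the shoelace formula and edge-length
sums; boolean intersection (for BOD) is delegated to Shapely.  The
test suite cross-checks both against a scanline rasterization oracle
(agreement within 0.5% on 100 seeded random simple polygons).

## Landmark detector

The detector is a heatmap-regression model: one heatmap per landmark
on a stride-4 grid over the 128 px standardized image, trained with
mean squared error against Gaussian targets (sigma 1 heatmap cell) and
decoded by sub-pixel center of mass over a 5x5 window around the peak.
The default backbone is a matched-filter head: a learned convolution
kernel per landmark (intensity and squared-intensity channels of a
17 px patch) evaluated at every grid position, plus a learned
per-landmark spatial prior map.  Patch features are whitened before
optimization — their raw covariance is so ill-conditioned that a
first-order optimizer otherwise spends all its steps on the leading
eigendirections — and the whitening is folded back into the stored
kernels, so inference sees plain pixels.  Fully-connected (`mlp`) and
densely-connected (`dense`) backbones are available as alternatives.

Decoded peaks are then refined by a two-stage cascade of per-landmark
ridge regressors mapping local appearance (a fine 17 px patch plus a
3x-pooled 51 px context window, with squared channels) to the residual
offset; the second stage is trained on smaller perturbations.  The
wide context window matters for the sternal notch and umbilicus, which
have almost no local texture and are localized mainly relative to the
body outline.  On the synthetic benchmark the cascade takes the mean
radial error from about 2.3 px to about 0.4 px; nipples, which carry a
distinct disk, localize to about 0.2 px.

Training is fully seeded (bit-identical weights across runs), records
the per-epoch training loss with the cohort-mean predictor's loss as
the baseline entry, and uses the standard 80-20 train-validation
split utility.  Optimizer, loss and architecture are this package's
own choices; no claim is made that they match any clinical system's
internals, whose trained weights and photographs are not available.

## Synthetic torsos

The generator renders grayscale frontal torsos (body ellipse, two
radially shaded breast mounds, bright nipple disks, Gaussian pixel
noise) with exact landmark ground truth and closed-form reference
values for every distance and index.  Footprints are superellipses
(|x/a|^n + |y/b|^n = 1, n >= 2, hence convex) sampled at 13 fixed
parameter angles that realize the ordinal convention; the inferior
semi-axis is b + ptosis_drop so drooping elongates the lower pole.
Asymmetry controls: a left-nipple displacement vector, a left/right
footprint area ratio, and the ptosis drop.  The physical scale
defaults to 53.76/width cm/px, placing SN-N near 21 cm independent of
raster size.

The analytic reference values are computed inside the generator with
independent arithmetic (inline shoelace, Sutherland-Hodgman convex
clipping for the mirrored-overlap area, plain distance formulas) and
never import the geometry module — they are the oracle the analysis
code is tested against, to 1e-6 cm on every generated sample.

The "true tape" lower-pole length models what a flexible tape measures
over the breast mound: the frontal chord inflated by the arc length of
a half-sine depth profile whose amplitude grows with the ptosis drop
(depth = 0.35 b + 0.9 ptosis).  It is a deliberately simple
one-parameter stand-in for 3-D breast shape; it guarantees the two
qualitative facts the agreement experiment needs — the proxy never
exceeds the true length, and the excess grows with ptosis — without
claiming anthropometric fidelity.

Cohort sampling emulates a post-surgical validation population, where
one breast has had tissue resected and asymmetries are large: nipple
malposition with sigma 2 cm (clamped so the nipple stays inside its
footprint), footprint area ratios log-normal with sigma 0.18 clipped
to [0.65, 1.5], ptosis uniform over 0-12 px (at 256 px scale), camera
roll sigma 2 degrees, plus small jitters of the body layout.  Every
sampled parameter is recorded in the cohort manifest.

What passing tests on this data do and do not show: they verify the
measurement chain end to end (rendering -> detection -> calibration ->
indices reproduces known ground truth), but the images lack skin
texture, lighting variation, pose change and anatomical diversity, so
detector accuracy numbers on synthetic torsos say nothing quantitative
about clinical photographs.

## Agreement statistics

For paired reference/comparator measurements the difference is
d = reference - comparator, so a positive bias means the comparator
under-reads.  Reported: bias = mean(d); limits of agreement
bias +/- 1.96 sd(d) with the sample (n-1) standard deviation and the
conventional fixed 1.96 multiplier (not a small-sample t quantile);
two-sided paired t-test; and proportional bias as ordinary least
squares of d on the per-pair mean with its r^2.  Degenerate inputs
(zero-variance differences, constant means) are flagged rather than
silently producing numbers.  The identity
bias = (upper LoA + lower LoA)/2 holds exactly by construction and is
asserted for every input.

The benchmark experiment pairs the generator's true lower-pole length
with the photo N-IMF proxy over a 100-torso cohort: the bias is
positive and the diff-vs-mean slope is positive (more ptotic breasts
are under-read by more), reproducing the qualitative behavior expected
of frontal-photo N-IMF measurement.

## Problem sizes and numerical choices

Default experiment sizes: detector benchmark 200 training and 50
held-out torsos at 128x128; agreement experiment 100 torsos at
256x256; oracle suites 100 random polygons at 10x rasterization scale.
Rasterization tolerances are 0.5% (polygon oracles) and 2% (overlap
rendering vs. polygon BOD).  Ties in the lowest-contour-point query
break toward smaller x; polygon orientation is normalized at
construction; the detector benchmark's rank correlation is Spearman's
rho pooled over the seven dimensionless indices across held-out
torsos.  Random state is always an explicit seed; there is no hidden
global RNG use.

## Known limitations

* Everything is 2-D: volumes, projections along the viewing axis, and
  true tape lengths over curved surfaces are out of reach by design.
* The N-S distance is a midline-perpendicular convention; systems that
  measure to a marked sternum point will differ.
* LBC and BCE formulas are declared conventions (the literature names
  these indices without fixing formulas); comparisons across software
  should verify convention compatibility first.
* The detector is validated only on synthetic torsos; applying it to
  photographs requires retraining on annotated photographs.
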