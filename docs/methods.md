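# Methods

`bovimetry` implements a non-contact body-measurement chain for cattle
built around a consumer structured-light depth camera, and validates it on
an analytic cow phantom whose seven body parameters are known in closed
form. This note documents the models, the defaults and the design choices,
in the order data flows through the pipeline.

## Virtual sensor

The camera is a 640 × 480 range imager whose performance depends on the
working distance *d*:

| d (mm) | lateral range (mm) | pitch (mm/px) | vertical step (mm) | BGN (mm) |
|-------:|-------------------:|--------------:|-------------------:|---------:|
| 400    | 415 × 310          | 0.65          | 0.7                | 1.1      |
| 1000   | 730 × 550          | 1.14          | 2.0                | 3.2      |
| 2000   | 1250 × 950         | 1.95          | 4.0                | 5.5      |

Values are linearly interpolated between the tabulated distances. BGN
(background noise) is the RMS roughness a flat reference exhibits after
plane removal.

The camera model is *orthographic with pitch*: pixels sample the scene on a
regular lateral grid of the distance-dependent pitch. The performance
table specifies pitch per distance directly, and residual perspective is
what the multi-view relocation step of the real procedure compensates, so a
pinhole model would add parameters without adding tested behaviour.

The physical measurement chain is applied in a fixed order (optics →
detector → disparity discretization):

1. geometric range along the view axis, nearest surface wins
   (self-shadowing between body parts falls out of this rule);
2. slope dropout: pixels whose surface inclination to the viewing ray
   exceeds 45° are void — this is both a nuisance (steep flanks vanish)
   and a measuring tool (the head border, below);
3. length non-linearity `r' = r · (1 + ν (r − d)/d)` with ν = 0.5% by
   default — the small proportional-to-length distortion this class of
   sensor exhibits;
4. additive Gaussian noise of the BGN standard deviation;
5. rounding to the vertical quantization step.

Slope dropout is evaluated on the geometric range, before noise, since
detectability is a property of the geometry, not of the noise realisation.

## Cow phantom

The phantom is an analytic solid: a torso with axial profile
`s(x) = (1 − |x/a|^6)^(1/2)` (flat-backed, rounded ends), elliptical
cross-section at the chest blending (tanh, centred at −0.18 a) into a
flat-topped superellipse (exponent 6) over the rump, a multiplicative
Gaussian waist just behind the front legs, Gaussian bumps for the hook
bones (hips), withers and tail head, four leg cylinders and an ellipsoidal
head separated from the torso (the neck is never measured and omitting it
keeps the head a separate segmentation component, as it effectively is for
a grazing posture).

Geometry constraints encode anatomy and detectability at the same time:

* the chest cross-section is exactly elliptical, so the ground-truth girth
  is an ellipse perimeter and the ellipse-fitting measurement is unbiased
  by construction of the geometry (not of the algorithm);
* the rump is flat-topped so the hook bones form genuine top-view height
  maxima at realistic lateral offsets; bump slopes are capped at ≈0.4 so a
  bump never drags the 45° dropout ring over its own apex;
* the tail-head bump is capped at 85% of the hook-bone curvature, making
  the "two strongest maxima in the caudal third" rule unambiguous (hook
  bones are anatomically the most prominent rump feature).

**Ground truth** is computed from the generating parameters only, never
from a rendering. Bump apexes ride on a curved base, so their exact
positions are found by extremizing the analytic surface numerically
(Nelder-Mead / bounded Brent, tolerance 1e-9); the chest section is the
interior minimum of the analytic flank profile; the chest girth is the arc
length of the analytic cross-section (quadrature, identical to Ramanujan II
at exponent 2); the head reference points follow from the closed-form 45°
tangency on the ellipsoid (`y* = h_y² / √(h_x² + h_y²)`).

**Presets.** The `calf` preset (torso half-length 300–400 mm, withers
height ≈ 0.5–0.7 m) is sized so the whole animal fits the 730 × 550 mm
field of view of a single 1 m capture — the scale of a young Holstein calf.
The `cow` preset is ≈1.5× larger and intended for the 2 m working distance.
All preset ranges are drawn uniformly per parameter from a seeded
generator; the same (preset, seed) pair always yields the same phantom.

**Posture.** A standing animal is not a rigid artefact: between captures it
flexes its legs and shifts its weight, and the posture it holds during one
session differs from its neutral pose. The simulator models this as a
trunk height offset (legs flex, hooves stay on the floor) plus a topline
pitch about the trunk centre, with a per-session component (sd 5 mm,
1.0°) and a smaller per-capture jitter (sd 2 mm, 0.3°). Ground truth
refers to the neutral pose, so posture propagates into the measured heights
exactly as live-animal posture does — and it is what makes the derived
parameters (average height, depth, and especially back slope, which divides
a height *difference* by the hips-withers length) progressively harder to
recover, reproducing the uncertainty-propagation ordering seen with live
animals. The lateral bone-to-bone distances and the girth are essentially
posture-invariant, which is why they stay tight.

## Calibration

Substitution calibration: five polystyrene-like reference hemispheres
(nominal radii 50–250 mm) are rendered through the sensor's own chain, ten
captures averaged pixelwise per artefact (averaging keeps the sphere fit on
the shallow, slope-clipped caps unbiased under noise), a least-squares
sphere (Coope linearisation + Gauss-Newton refinement of geometric
residuals) is fitted to each cap, and a linear model
`nominal = scale · fitted + offset` is derived. The correction acts on a
frame's vertical values as deviations from the working distance. A linear
model cannot cancel the quadratic part of the length non-linearity, so a
small realistic residual error remains in heights — as it does for the
physical sensor.

BGN estimation removes a total-least-squares plane (residuals orthogonal to
the surface, hence tilt-invariant) and reports the RMS residual.

## Filtering and landmarks

Frames are leveled to the floor plane fitted on low pixels; the body is the
largest connected component above a height threshold (300 mm from above,
150 mm from the side). From above, the void ring caused by the 45° cutoff
on the steep flanks is counted as body, so the silhouette spans the true
width; from the side the void background would bridge disjoint parts
(torso/head) and is excluded.

Gradient and mean-curvature maps are computed on a Gaussian-smoothed
elevation field. Convention: surfaces convex toward the sensor have
negative mean curvature, so anatomical prominences are null-gradient,
negative-curvature clusters. Defaults, all configurable and echoed in the
run log:

* detection smoothing σ = 11 mm — large enough that the gradient noise at
  the worst tabulated BGN stays well under the null-gradient tolerance,
  small enough that the masked guard band around voids (2σ) stays clear of
  the hook-bone apexes;
* null-gradient tolerance ε = 0.02 mm/mm, with cluster hysteresis growth to
  2ε (a maximum's cluster survives gradient noise without loosening the
  seed criterion);
* a second, lightly smoothed field (σ = 4 mm) refines each detected apex by
  a local quadratic fit — heavy smoothing displaces apexes down-slope, and
  the refinement removes that bias (and most of its size-dependence);
* maps are masked within one smoothing stencil of void pixels.

Search windows: hip pair = two strongest maxima in the caudal third
(≥ 5 pitches apart), withers = strongest in the cranial third, tail head =
strongest caudal of the hips.

The chest section is detected on the side view as the interior minimum of
the per-column *topline* profile (the flank's upper visible edge). For a
vertically symmetric section the full height extent is proportional to the
topline height, and the topline is immune to the legs occluding the belly
line, so this variant of the "thinnest flank section" rule is the default
(the full-extent profile is also available). The discrete minimum is
refined by a parabolic fit, and ties go to the more cranial position.

The hoof-floor interface is the row of strongest second derivative of the
leg silhouette's width profile; among comparably strong responses the
lowest is taken (the silhouette also has a corner where the leg meets the
trunk).

The head border is the valid/void boundary of the nearest-to-camera
component in the front view — by the slope-cutoff argument it lies exactly
on the 45° line of the face. The boundary is split into left/right arcs
about the face axis and each arc's median point (robust to jagged void
edges) is the reference point.

## Body parameters

* hip distance, body length: floor-projected Euclidean distances between
  the respective landmarks;
* front/back height: withers and hip-pair-midpoint heights over the datum
  (leveled floor; the hoof-floor landmark when the floor is not
  reconstructed);
* average height: midpoint of front and back height;
* back slope: `arctan((front − back) / hips-to-withers length)`, positive
  when the withers stand higher; the hip reference point of the length is
  the hip-pair midpoint;
* chest girth: top and side views are merged (nominal poses; optional
  trimmed-ICP refinement, rigid only), a 30 mm slab about the chest section
  is projected to the section plane, an ellipse is fitted with two
  absolute-residual trimming passes (15 mm, 8 mm — stray leg/floor returns
  and bump tails), and the perimeter is Ramanujan's second approximation
  (error < 1e-6 at these aspect ratios). Angular coverage of the fitted
  ellipse is reported; below 40% a warning is attached;
* depth: average height minus the fitted section's vertical extent (the
  two conserve their sum by definition);
* head size: distance between the two border midpoints (an apex-to-border
  head length is also computed).

Each parameter is finally the mean over ten repeated capture cycles; an
occasional cycle whose landmarks cannot be assigned is dropped with a
warning (a run fails if fewer than half the cycles survive).

## Uncertainty budget

GUM-style: each source is converted to a standard uncertainty with its
distribution coefficient (rectangular 1/√3, triangular 1/√6, normal 1),
percent sources resolve against the measurand length, uncorrelated sources
combine as a root sum of squares, and the expanded uncertainty is
`U = k·√Σ(t·s)²` with k = 1.645 (90% two-sided). Averaging n repeats
divides random sources by √n; alignment (Abbe) errors are systematic and
exempt. The packaged budgets (manual meter, single capture, ten averaged
captures) give U = 3–15 mm for ten averaged depth-camera measurements over
the 400–2000 mm working range. Printed 10-measure figures in such budgets
are rounded (half-up, one decimal): 2.4/√10 = 0.759 → 0.8. The √n rule
does not exactly reproduce every tabulated 10-measure figure (e.g.
0.65/√10 ≈ 0.21 against a tabulated 0.3, which likely includes a
repositioning contribution); the rule is implemented as stated and the
discrepancy documented rather than matched. The manual budget's tabulated
upper range is likewise narrower than a worst-case-measurand RSS of its
sources; the package reports what the stated formula yields.

## Validation studies and their scale

`bovimetry.validation` runs two studies, also used by
`scripts/acceptance.py`:

* **recovery cohort** — 20 random calf phantoms, 10 capture cycles each at
  1 m, full chain including its own substitution calibration; recovered
  values are regressed on ground truth per parameter. This size keeps the
  study a few minutes on one core while the regression standard errors are
  already an order of magnitude below the acceptance bands.
* **repeat dispersion** — 50 single-capture extractions of one animal; the
  per-parameter scatter is compared with the single-measure budget's
  combined standard uncertainty.

## What passing these studies does and does not show

The phantom reproduces the *geometry* of the measurement problem (curved
single-valued surfaces, slope dropout, occlusion, noise, quantization,
distortion, stance variation) but not everything about real barns: no coat
or dirt reflectance effects, no breathing or locomotion during a capture,
no perspective floor shadowing, no operator mis-aiming, and landmark
prominences far cleaner than the anatomy of a young calf. Passing the
recovery study shows the chain is internally consistent and unbiased at
realistic noise; it does not certify field accuracy on live animals.

## Known limitations

* The correction model is linear per axis; distance-dependent calibration
  is available only by calibrating per working distance.
* ICP refinement is trimmed point-to-point (Kabsch) with an annealed
  correspondence cutoff; canonical orthogonal views share only a thin
  overlap band, so the pipeline trusts the nominal simulation poses by
  default and refinement is exercised on overlapping same-view captures.
* The q-exponent blend between chest and rump sections creates a narrow
  steep band mid-back that the slope cutoff voids; it lies away from every
  landmark window but is an artefact of the parameterisation, not anatomy.
* `segment_body` assumes a single animal in the frame.
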