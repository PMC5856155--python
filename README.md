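# bovimetry

Non-contact body measurement of cattle from structured-light depth
captures, validated end to end on simulated cow phantoms with closed-form
ground truth.

Frequent checks of a calf's or cow's body dimensions (withers and hip
height, back slope, hip distance, body length, chest girth, body depth,
head size) support growth and welfare monitoring, but manual taping
stresses the animal. A low-cost 640 × 480 structured-light depth camera
can replace the tape: the animal is captured from four viewpoints (left,
right, top, front), the depth frames are corrected with a substitution
calibration on reference hemispheres, leveled to the floor, segmented, and
filtered into gradient/curvature maps from which anatomical reference
points are extracted; each body parameter is the average of ten repeated
captures and carries a GUM-style expanded uncertainty

```
U = k · sqrt( Σᵢ (tᵢ · sᵢ)² ),     k = 1.645 (90% confidence)
```

where the sᵢ are the uncertainty sources (lateral/vertical resolution,
background noise, length non-linearity, Abbe error, reference-point
localization) and tᵢ their distribution coefficients (1/√3 rectangular,
1/√6 triangular, 1 normal).

Landmark rules, in the field's terms: hips, withers and tail head are
local surface maxima (null gradient, negative mean curvature); the chest
girth section is the thinnest flank section (null gradient, positive
curvature of the flank profile); the hoof–floor interface is the strongest
second-derivative response of the leg silhouette; the head reference points
sit on the 45° maximum-detectable-slope border of the face. The girth
itself is the Ramanujan-II perimeter of an ellipse fitted to the chest
cross-section of the merged top + side clouds, and body depth is the
average height minus that section's vertical extent.

Because no public depth captures of measured animals exist, the package
ships a first-class simulator: a parametric cow phantom (superellipsoid
torso, Gaussian bone prominences, waist, legs, head, stance variation)
whose seven parameters have analytic ground truth, rendered through a
virtual sensor with distance-dependent pitch, vertical quantization,
background noise, 45° slope dropout, occlusion and length non-linearity.

## Worked example

```python
from bovimetry import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(preset="calf", seed=7, repeats=10))
truth = res.phantom.truth
for name, value in res.aggregate.as_dict().items():
    print(f"{name:16s} {value:8.1f}   truth {getattr(truth, name):8.1f}"
          f"   sd {res.aggregate.dispersion[name]:5.2f}")
```

prints (units mm, back slope in degrees):

```
hip_distance        163.6   truth    164.9   sd  1.02
body_length         376.5   truth    377.0   sd  1.27
front_height        602.7   truth    592.3   sd  1.27
back_height         598.4   truth    588.2   sd  1.26
average_height      600.5   truth    590.3   sd  1.19
back_slope            0.8   truth      0.8   sd  0.16
chest_girth        1025.5   truth   1024.4   sd  1.44
depth               249.8   truth    238.2   sd  1.32
head_size           101.6   truth    103.3   sd  0.07
```

The lateral, bone-to-bone parameters (hip distance, body length, head
size) and the girth land within a couple of millimetres; the heights absorb
the animal's stance (this phantom stood ≈10 mm taller than its neutral
pose during the session), which is exactly the behaviour the uncertainty
budget's localization and posture terms describe. The per-repeat scatter (`sd`)
stays far below the single-capture budget, which is why averaging ten
captures brings the expanded uncertainty down to 3–15 mm.

The same machinery is available from the shell:

```sh
bovimetry simulate --preset cow --views left,right,top,front --distance 2000 --seed 3 --out sim/
bovimetry calibrate --clouds spheres/ --nominals radii.yaml --out correction.yaml
bovimetry budget --name kinect-10 --end upper --measurand 2000
bovimetry run --preset calf --seed 7 --repeats 10 --out session/
bovimetry compare --reference manual.csv --measured kinect.csv --out stats.csv
```

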