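# lrdseg

Level-set segmentation of 2-D images with intensity inhomogeneity, with
joint estimation of the multiplicative bias field and a local difference
field.

Slowly varying intensity shading — the *bias field* of MRI, caused by RF
coil non-uniformity — smears the intensity distributions of tissue
classes and defeats global clustering or thresholding. `lrdseg`
implements an active-contour model for this setting: the measured image
is modeled as

```
I(x) = b(x) · J(x) + d(x) + n(x)
```

where `J` is piecewise constant (`J ≈ c_i` on each class `Ω_i`), `b` is
a smooth multiplicative bias, `d` is a locally estimated additive
difference between the measurement and the `b·J` approximation, and `n`
is noise. Segmentation minimizes a local clustering energy over a
level-set partition,

```
E = Σ_i Σ_x u_i(x) ∫ K_σ(y−x) (I(x) − b(y) c_i − d(y))² dy
    + α P(φ) + β ∫ |∇H(φ)|
```

with a truncated Gaussian window `K_σ`, smoothed-Heaviside memberships
`u_i(φ)`, a distance-regularization term `P(φ) = ½∫(|∇φ|−1)²` that keeps
`φ` close to a signed distance function without re-initialization, and a
contour-length penalty. The unknowns `(c, b, d)` have closed-form
alternating updates; `φ` evolves by an explicit gradient flow. Clamping
`d ≡ 0` recovers the classical local-intensity-clustering baseline,
available as `baseline_li=True` for comparison. Both two-phase
(object/background) and three-phase (e.g. WM/GM/CSF-like) formulations
are provided, the latter with two coupled level-set functions.

The package is aimed at method developers and students of variational
segmentation: every behavior is testable without external data through a
synthetic phantom generator with known ground-truth labels and bias
fields.

## Worked example

```python
import numpy as np
from lrdseg import ModelParams, segment_two_phase
from lrdseg.metrics import multiclass_metrics
from lrdseg.phantoms import generate, get_spec

phantom = generate(get_spec("tshape-bias"))       # 128x128, bias 0.8-1.2, noise sd 5
rows, cols = np.mgrid[0:128, 0:128]
seed = np.hypot(rows - 40, cols - 55) < 12        # small circle inside the object

result = segment_two_phase(phantom.image, seed, ModelParams())

truth = np.where(phantom.true_labels == 2, 1, 2)  # object = class 1
report = multiclass_metrics(truth, result.labels, class_id=1)
bias_r = np.corrcoef(result.bias.b.ravel(), phantom.true_bias.ravel())[0, 1]

print(f"converged: {result.converged} after {result.iterations_run} iterations")
print(f"class means: {result.bias.c.round(2)}")
print(f"object overlap: DSC={report.dsc:.4f}  JS={report.js:.4f}")
print(f"bias-field correlation with truth: r={bias_r:.4f}")
```

prints

```
converged: True after 150 iterations
class means: [169.54  60.41]
object overlap: DSC=1.0000  JS=1.0000
bias-field correlation with truth: r=0.9941
```

The phantom's true class means are 170 and 60 (up to the mean-1 bias
normalization); the estimated means, the label map (Dice and Jaccard of
1.0 against the ground truth) and the estimated bias field (Pearson
r = 0.994 against the true ramp) are all recovered from a biased, noisy
image seeded with a single small circle.

The same pipeline from the shell:

```sh
lrdseg phantom --preset tshape-bias --seed 7 -o out/
lrdseg segment out/image.tif --init "circle 40,55,12" -o seg/
lrdseg evaluate seg/labels.png out/labels.png --seg-class 1 --gt-class 2
```

```
js,dsc,rfp,rfn,n_gt,n_seg,n_overlap
1.000000,1.000000,0.000000,0.000000,4025,4025,4025
```

`lrdseg segment --classes 3 --init ... --init2 ...` runs the three-phase
model; `lrdseg correct` writes only the bias field and bias-corrected
image.

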