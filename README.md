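# semreg — semantically guided two-step B-spline registration

Deformable image registration estimates, for a *fixed* image `I_f` and a
*moving* image `I_m`, a dense displacement field `V ∈ R^{2×H×W}` such that
`I_m(x + V(x))` aligns with `I_f(x)`.  When the initial misalignment is
large — fast-moving structures in video, end-diastole vs end-systole in
cardiac MRI, face parts across subjects — intensity-driven methods lose
track in low-texture regions.  `semreg` implements a weakly supervised deep
registration model for that regime, aimed at researchers in medical image
analysis and computer vision who have segmentation labels for their
*training* images only.

The model has three jointly trained parts:

* a compact **U-Net** (≈200k parameters, shared between the two images)
  that turns each greyscale image into per-pixel class probabilities at
  half resolution, supervised with a weighted cross-entropy
  `L_semantic = −(1/N) Σ_j w_{t(x_j)} log f_{t(x_j)}(x_j)` whose label
  weights `w_l ∝ sqrt(1/freq_l)` protect small structures;
* a **two-step cascade of registration networks**: each RegNet predicts a
  coarse control grid of displacements, densified into a smooth field by
  the cubic-B-spline construction (nearest upsampling + three unit-stride
  average poolings), the second step seeing the moving features already
  warped by the first field (`V1 ∘ f_m`); the fields combine additively or
  by composition `V(x) = V2(x) + V1(x + V2(x))`;
* a **training objective**
  `L = λ_s L_semantic + L_deform + λ_r L_regular`, where `L_deform` is the
  weighted L1 distance between the fixed one-hot segmentation and the
  warped moving one, and `L_regular = ‖V − V_smooth‖²` penalises deviation
  from a locally smoothed copy of the field (λ_s = 1.0, λ_r = 0.001, Adam,
  learning rate 1e-3, first-moment decay 0.97).

At inference no labels are needed.  Evaluation reports per-structure Dice,
symmetric contour distance, and Jacobian-determinant summaries (std and the
fraction of folded pixels, det ≤ 0).  A diffeomorphic variant integrates
stationary velocity fields by scaling-and-squaring.  Everything — including
the convolutional networks and backpropagation — runs on numpy; no GPU or
deep-learning framework is required, and all runs are bit-reproducible
under fixed seeds.

A synthetic-data module generates image/label pairs with known
ground-truth B-spline deformations (cardiac-like ring scenes or face-like
part scenes) so the full pipeline is testable end-to-end with no downloads.

## Worked example

```python
import numpy as np
from semreg import SceneSpec, SemanticGuidedRegistration, TrainConfig, generate_pair

spec = SceneSpec(image_size=(32, 32), magnitude=5.0)
train = [generate_pair(spec, seed) for seed in range(40)]
test = [generate_pair(spec, 1000 + seed) for seed in range(10)]

config = TrainConfig(
    epochs=30, batch_size=8, base_channels=8,
    regnet_widths=(16, 32, 64), regnet_widths_single=(24, 48, 96), seed=0,
)
model = SemanticGuidedRegistration(train, config, val_pairs=test[:4])
fit = model.fit()
print(fit.summary())

_, before = fit.evaluate(test, zero_field=True)
_, after = fit.evaluate(test)
print(f"mean Dice unregistered: {before['mean_dice']:.3f}")
print(f"mean Dice registered:   {after['mean_dice']:.3f}")
```

Output (≈15 s on one CPU core):

```
Semantically Guided Registration Results
============================================
mode:            two-step
guidance:        semantic (lambda_s=1)
combine mode:    transform
B-spline kernels: 5/3; smoothing 3x3 x2
U-Net params:    49,244
RegNet params:   217,124
epochs trained:  30 (batch 8, lr 0.001, beta1 0.97)
final losses:    total=0.0815 (semantic=0.0676, deform=0.0140, regular=0.0001)
best val Dice:   0.7260 (epoch 29)

mean Dice unregistered: 0.525
mean Dice registered:   0.765
```

The unregistered Dice (0.525) is the initial overlap of the held-out pairs
under deformations with a 5 px peak on 32×32 scenes; after training, the
predicted fields recover most of that misalignment (0.765) with no folded
pixels.  `fit.register(fixed, moving)` returns the per-pair fields and
warped outputs; `fit.save(path)` writes a self-describing checkpoint.

The same workflow is available from the shell:

```sh
semreg synth --n-pairs 20 --seed 0 --out-dir data/
semreg train --manifest data/manifest.csv --checkpoint model.npz --set epochs=30
semreg register --fixed f.png --moving m.png --checkpoint model.npz --out-dir out/
semreg evaluate --manifest data/manifest.csv --checkpoint model.npz --out report.json
```

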