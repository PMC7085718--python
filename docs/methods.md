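# Methods

## The registration model

`semreg` estimates a dense displacement field between two greyscale images
of the same scene class when the initial misalignment is large — the regime
where intensity-driven optical-flow-style methods lose track.  The model is
weakly supervised: segmentation label maps are required during training
only; at inference the two images suffice.

Three stages, trained jointly end-to-end:

1. **Semantic features.**  A compact U-Net (11 convolutions, 3×3 kernels,
   three stride-2 stages, two skip connections, ≈195k parameters at the
   default width) maps an image `I ∈ R^{H×W}` to softmax class
   probabilities `f ∈ [0,1]^{L×H/2×W/2}` at half resolution.  One network
   instance processes both images (shared weights).  It is supervised with
   a weighted cross-entropy

       L_semantic = −(1/N) Σ_j w_{t(x_j)} log f_{t(x_j)}(x_j),

   where the label weights are the square root of the inverse class
   frequency, normalised to mean 1 so the loss weight λ_s stays meaningful
   across label sets.

2. **Two-step B-spline registration.**  The concatenated feature maps
   (2L channels) enter a strided convolutional RegNet that predicts a
   2-channel control grid of displacements at a control-point spacing of 4
   feature pixels (8 image pixels; the spacing is the product of the two
   stride-2 stages).  The grid is densified to a smooth field by
   nearest-neighbour replication followed by **three unit-stride average
   poolings** — the recursive box-filter construction of the cubic cardinal
   B-spline.  The first step uses a large pooling kernel (coarse, large
   motion), the second a smaller kernel (refinement); the second network
   sees the moving features already warped by the first field, and the two
   fields are composed.  Composition is either `additive`
   (`V = V1 + V2`) or `transform`
   (`V(x) = V2(x) + V1(x + V2(x))`), which makes a single warp by `V`
   equal to warping by `V1` then `V2`.  Fields are predicted at feature
   (half) resolution and bilinearly rescaled ×2 — doubling the displacement
   values — before full-resolution warping.  Every prediction head is
   zero-initialised so training starts at the identity transform.  The
   default two-network cascade carries ≈1.92M parameters; the single-step
   variant uses one net of ≈2.16M (matched budget).

3. **Losses.**  With one-hot label channels `S` warped bilinearly (soft
   warping keeps the objective differentiable in the field),

       L_deform  = (1/L) Σ_l w_l · mean_x |S_f,l(x) − T(V, S_m,l)(x)|,
       L_regular = mean ‖V − V_smooth‖²,
       L_total   = λ_s (L_sem,fixed + L_sem,moving) + L_deform + λ_r L_regular,

   where `V_smooth` is two unit-stride 3×3 average poolings of `V`.
   Defaults: λ_s = 1.0, λ_r = 0.001; Adam with learning rate 1e-3 and
   first-moment decay 0.97.  All losses are pixel means, which keeps the
   scalar weights resolution- and batch-invariant.

A **diffeomorphic** mode reads each network output as a stationary velocity
field and integrates it by scaling-and-squaring (divide by 2^k, compose
with itself k times; default k = 6) before use, which guarantees positive
Jacobian determinants for moderate velocities at some cost in alignment
accuracy.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kernel1` / `kernel2` | 5 / 3 | pooling kernel of each step, i.e. the B-spline scale; chosen ≈5% and 3% of the largest image dimension (19/11 would suit ~320 px images) |
| `smooth_kernel`, `smooth_passes` | 3, 2 | regulariser smoothing (pixels) |
| `lambda_s`, `lambda_r` | 1.0, 0.001 | loss weights |
| `learning_rate`, `beta1` | 1e-3, 0.97 | Adam settings |
| `base_channels` | 16 | U-Net width (≈195k parameters) |
| `regnet_widths` | (48, 96, 192) | per-step RegNet widths (≈0.96M each) |
| control spacing | 8 px | fixed by the two stride-2 RegNet stages |

## Numerical engine

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine on `numpy` float32 arrays (`semreg.nn`) with
im2col convolutions, separable cumulative-sum box filters (replicate
padding, so constants are preserved exactly — the partition-of-unity
property of the spline construction), differentiable bilinear sampling with
border clamping (clamped samples get zero positional gradient), softmax and
the reductions the losses need.  Every operation's gradient is tested
against central finite differences.  All randomness flows from explicit
`numpy` `SeedSequence`s and BLAS is pinned to one thread, so training runs
are bit-reproducible.

Numerical conventions: displacement fields are `(2, H, W)` arrays in pixel
units, channel 0 = x (column), channel 1 = y (row), 0-based, origin
top-left, backward (pull) warping `out(x) = src(x + D(x))`; out-of-bounds
samples clamp to the border (zero-fill would leak artificial gradients into
the loss near edges).  Jacobian determinants of `x → x + D(x)` use central
differences in the interior and one-sided differences at borders, unit
spacing.  Probabilities are clipped to `[1e-7, 1]` before logs.  A
non-finite loss term aborts training with a diagnostic rather than
continuing from a poisoned state.

## Synthetic data: what it emulates, what it does not

`semreg.synthetic` generates the training regime the method targets with no
external data: multi-structure label maps (a cardiac-like scene — blood
pool nested in a myocardium ring plus an adjacent ventricle — or a
face-like scene with small parts inside a large ellipse), intensity images
rendered from the labels with per-structure multiplicative contrast jitter
in [0.7, 1.3] and Gaussian noise σ = 0.02 (inter-subject appearance
variation), and ground-truth deformations drawn from the model's own
cubic-B-spline family (control spacing 8 px), rescaled to a configurable
peak magnitude and rejected if any Jacobian determinant is non-positive.
The default desk-scale regime is 64×64 images, L = 4 labels and peak
displacements of 10 px — large relative to the ~12 px structures, i.e. the
large-deformation setting.

The generating field is stored in the backward fixed→moving convention, so
it plugs directly into warping and evaluation, and the generator's
deformation family matches the model's: exact recovery is representable and
the recovery experiment is well-posed.  What the generator does *not*
emulate: real anatomical texture (structures are piecewise-constant plus
noise), occlusions, through-plane motion, or intensity non-uniformity.
Passing the synthetic recovery tests therefore demonstrates that the
estimator and its training objective work as designed, not that the trained
weights transfer to any real dataset.

Because the background is textureless noise, the true displacement is
unidentifiable there and a weakly supervised model correctly predicts
near-zero background motion.  Endpoint error against the generating field
is therefore reported over the structure foreground of the fixed label map;
the whole-image ratio is reported alongside for transparency.

## Evaluation

Per structure (background excluded): Dice overlap of the fixed mask against
the nearest-neighbour-warped moving mask, and the symmetric mean contour
distance between 4-connectivity inner boundaries (Euclidean
point-to-contour distances via distance transforms).  Structures empty in
the fixed image, or whose warped mask is empty, are excluded from the
per-image means with a warning.  Field regularity is summarised by the
standard deviation of the Jacobian determinant and the fraction of pixels
with determinant ≤ 0.  Two empty masks have Dice 1 by convention; contour
distance is undefined for empty masks.

## Problem sizes used in the shipped experiments

CPU-scale sizes, stated here as the package's own experimental design:

* **Recovery experiment** (tests and `scripts/acceptance.py`): 96 training
  / 16 held-out pairs at full network widths, 24 epochs, batch 8.  Typical
  outcome: mean Dice rises from ≈0.64 (unregistered) to ≈0.86, foreground
  endpoint error ≈47% of the initial foreground displacement, no folded
  pixels.
* **Ablation trends**: 24 training / 8 test pairs per seed, width-reduced
  networks (`base_channels=8`, widths (16,32,64) / single-step (24,48,96)),
  50 epochs, 3 seeds; directions asserted on seed means: two-step ≥
  single-step, guided ≥ not-guided, separate ≥ shared RegNet weights, and
  the diffeomorphic mode does not increase Dice while not increasing the
  folded-pixel fraction.  The margins between variants are small at this
  scale (the guidance effect is the largest); the runs are deterministic,
  so the inequalities are reproducible rather than statistical claims.

## Design choices where the design was open

* Upsampling before the pooling cascade is nearest-neighbour replication;
  together with three box filters this is the recursive cardinal-spline
  construction.  Replicate padding everywhere keeps constants invariant.
* The transform-mode composition formula was chosen so that one warp by the
  combined field equals two-stage warping (verified against a two-warp
  oracle).
* Ground-truth labels are matched to the half-resolution feature output by
  nearest-neighbour downsampling (preserves label identity).
* The deformation loss reuses the semantic-loss class weights; both losses
  are means, not sums.
* The semantic loss is applied to both images' predictions (the extractor
  is shared and both predictions exist).
* Control-point spacing is the product of the RegNet's stride-2 stages
  (a power of two) rather than a function of the pooling kernel; the kernel
  remains the free scale parameter.
* Activation is LeakyReLU(0.1) with no normalisation layers, recorded in
  the checkpoint config.
* Model selection during training tracks mean Dice on a held-out split when
  one is provided (`use_best_weights()`); the final-epoch weights are the
  default.
* `pretrain_unet` reproduces the two-phase variant (U-Net first trained on
  the semantic loss alone, then joint training with `freeze_unet`
  optionally keeping it fixed).

## Known limitations

Only 2D single-channel images are supported (the contracts are written so a
3D extension changes shapes, not semantics).  Pure-numpy training is
CPU-bound: the shipped experiments are minutes, not hours, but scaling to
hundreds of epochs on large datasets is out of scope.  The identical-pair
behaviour of a trained model retains a small residual field (~15% of the
mean training displacement at desk scale): identical inputs are
off-distribution and nothing in the objective enforces antisymmetry.
Sub-pixel label warping during evaluation quantises at mask boundaries, so
even the generating field does not always score Dice exactly 1 on thin
structures.
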