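# Methods

## Model

The classifier is a Vision Transformer whose patch-embedding stage is made
exactly invariant to quarter rotations. Given a square image
`X ∈ [0,1]^{H×W×C}`, the model:

1. standardizes the input pointwise (`(X − 0.5)/0.25`, see *Numerical
   choices*);
2. forms the k quarter-rotated copies `X^(j) = rot90^{j·(4/k)}(X)`,
   `k ∈ {1,2,4}` (default 4); rotation by multiples of 90° is an exact
   pixel permutation — no interpolation, no resampling;
3. optionally applies a depth-wise 3×3 + pointwise 1×1 convolution stem to
   each copy (zero same-padding, spatial size preserved, no nonlinearity);
4. cuts each copy into a row-major grid of P×P patches, flattens them
   (pixel-row-major, channel last), and projects them with one **shared**
   affine map `E` to D-dimensional tokens;
5. averages the k token sequences elementwise;
6. prepends a learnable class token, adds learnable position embeddings,
   and runs L pre-norm transformer blocks
   (`x + MHSA(LN(x))`, then `x + MLP(LN(x))`, GELU activation, dropout on
   the attention weights only);
7. applies a final layer norm and a linear head to the class token;
   softmax over the two classes (tumor = positive).

**Why the average is invariant.** Rotating `X` by one quarter turn maps
the set `{X^(j)}` for k=4 onto itself (a cyclic shift). Steps 3–4 are
applied per copy, so the per-branch token sequences of `rot90(X)` are a
permutation of those of `X`, and their elementwise mean is identical.
Everything downstream consumes only the mean, so the logits are invariant.
In floating point the branch sums occur in a different order, leaving
deviations at the 1e-7 level for the full-size model (tolerance used in
tests: 1e-4). The argument requires only that steps 1–3 commute with the
permutation of branches, which pointwise standardization and a
per-copy-applied convolution do.

**Consequences used as test oracles.** (a) With k=1 the model is
identically the no-rotation variant: with shared weights the logits agree
bit-for-bit. (b) Rotation averaging reuses one projection, so it
contributes zero parameters: the rotation-averaged model and its
no-averaging ablation always have equal parameter counts, for every
configuration. (c) The stem adds parameters, so removing it strictly
reduces the count.

## Architecture family and hyperparameters

Four presets: the rotation-averaged model (`rvit`), a larger conventional
baseline (`base_vit`), and one ablation for each novel component
(`rvit_variant1`: no rotation averaging; `rvit_variant2`: no stem).
Reference settings: 224×224×3 inputs, 16-px patches; `rvit`-family D=142,
L=10, h=10, MLP 480; `base_vit` D=768, L=12, h=12, MLP 1024; attention
dropout 0.1; Adam lr 1e-3, weight decay 1e-2 (L2 added to the gradient,
i.e. classic Adam weight decay), batch 32, default 25 epochs, stratified
80/20 train/validation split.

Since 142 is not divisible by 10 heads, the per-head width is
`floor(D/h) = 14`; the attention operates at inner width `h·d_h = 140` and
the output projection maps 140 → 142. This choice (and the unspecified
stem width, default 8 channels) means absolute parameter counts are
implementation-defined; only the equality/ordering relations above are
contractual, and only those are asserted.

## Training

Plain minibatch Adam on cross-entropy, all randomness (init, split,
shuffling, dropout) driven by explicit seeds; per-epoch train/val loss and
accuracy are recorded and the best-validation checkpoint is restored at
the end (final-epoch metrics remain in the history). Two additions proved
necessary for reliable from-scratch training of these small transformers
on small datasets:

* **Input standardization** (step 1). With raw [0,1] pixels the token
  stream is dominated by a DC component; in pilot runs the optimizer then
  reliably converged to the class prior and actively suppressed the
  input-dependence of the logits. Centering/scaling the input removes the
  attractor.
* **Global gradient-norm clipping** (default 1.0, `TrainConfig.grad_clip`,
  0 disables). At batch size 32 a cold-started transformer occasionally
  produces a gradient spike that throws Adam irreversibly out of a learned
  basin; capping the global norm removes these excursions. No learning-rate
  schedule is used.

## Synthetic phantoms

Each phantom is a bright smooth-edged disk ("brain", radius 0.42·S, ±2 px
center jitter, intensity ~0.65 over a 0.15 background) plus low-frequency
Gaussian-filtered texture (amplitude 0.10, σ = S/10, supported on the
disk) and i.i.d. Gaussian pixel noise (σ 0.03), clipped to [0,1]. Positive
images add one soft-edged bright ellipse (default semi-major axis 9–15 px
at S=64, axis ratio 0.4–0.7, intensity lift 0.45) at a uniformly random
center inside the disk, with orientation drawn uniformly on [0°,360°) or
from a configurable range; the exact lesion mask is retained. The
generator is a pure function of (spec, seed).

Defaults were fixed in a pilot so that lesion presence is detectable by
simple intensity features (a max-intensity threshold separates the default
population essentially perfectly; raw-pixel logistic regression reaches
≈0.9): the phantoms test the *pipeline and the invariance machinery*, not
the hard part of tumor recognition. What passing tests on phantoms does
**not** show: performance on real MRI (no anatomy, no acquisition
artifacts, no class overlap, 2-D only).

For the rotation-robustness benchmark arm a second population makes
orientation matter: fainter (lift 0.25), more elongated (ratio 0.3–0.5)
lesions against stronger texture (0.18), with orientation restricted to
±15° of horizontal. Peak brightness is then ambiguous and a classifier
must use shape features at the trained orientation. The benchmark
evaluates accuracy on the held-out *biased* set rotated by 0/90/180/270°:
rotating this set shifts the lesion-orientation distribution into the
untrained range, which is the failure mode being measured. (Rotating a
uniform-orientation set would leave the orientation distribution unchanged
and the expected accuracy equal at all angles, so it cannot expose the
effect.) The rotation-averaged model predicts identically at all four
angles per image, architecturally; the non-averaged variant shows an
accuracy range of 0.01–0.10 across seeds in pilots.

## Scaled-down study sizes

Desk-scale experiments use 64×64 single-channel phantoms, patch 8, D=64,
L=4, h=4, MLP 256 (~240k parameters), 500 images, batch 32, 10 epochs for
the rotation-averaged arm and 20 epochs for the fainter-lesion benchmark
arm (the harder task needs the longer run to learn reliably from a cold
start). With the reference Adam settings the rotation-averaged arm reaches
best validation accuracy 0.95–1.00 across seeds.

## Grad-CAM for token grids

Embedding dimensions are treated as channels and non-class tokens as
spatial locations: per-channel weights are the token-averaged gradients of
the target-class *logit* (not the softmax), the weighted activations are
rectified, normalized to [0,1] (an identically zero map stays zero),
reshaped to the (H/P)×(W/P) grid and bilinearly upsampled. Attribution
targets the tokens *entering* the last encoder block: downstream of that
block only the class token reaches the logit (per-token final norm + head
on token 0), so gradients with respect to the block's output patch tokens
are identically zero. For rotation-averaged models the explained scalar is
itself rotation-invariant; the default map is drawn in the unrotated
frame, and a `branch_average` mode averages the map re-expressed in each
branch's own frame.

## Numerical choices

* float32 throughout; exact (erf) GELU; softmax with max-subtraction;
  layer-norm ε 1e-5; Adam ε 1e-8, β = (0.9, 0.999).
* Input standardization constants 0.5/0.25 are fixed (not data-dependent)
  so that invariance and reproducibility do not depend on batch statistics.
* Metric reports round half-up to 3 decimals; zero-denominator metrics are
  `nan` ("undef" in tables, `null` in JSON), never silently 0.
* `confusion_from_rates` reconstructs counts with half-up rounding of
  `sens·n_pos` and `spec·n_neg`.
* Ties in argmax resolve to the lower class index (NumPy convention).
* Checkpoints are a single `.npz` with the config embedded as JSON;
  loading rebuilds the model and restores weights exactly.

## Known limitations

* Invariance is exact only for multiples of 90°; arbitrary-angle
  robustness is out of scope (and arbitrary-angle rotation of a raster
  image is necessarily lossy).
* The ~1.7M-parameter gap reported elsewhere between the rotation model
  and its stem-less ablation is not reproducible from the published
  architecture description; parameter-count assertions are therefore
  relational, not absolute.
* Training is CPU-bound NumPy; the full 224-px presets train only at
  dataset scales far below the reference experiments. The scaled-down
  study is a property check, not a reproduction of reported accuracies.
* The saliency map attributes through the token grid of the unrotated
  frame; it is not itself rotation-equivariant (only the explained logit
  is invariant).
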