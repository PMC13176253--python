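# Methods

## Problem and model

`mscfnet` performs joint nucleus instance segmentation and virtual staining
on IHC-like RGB tiles.  A shared convolutional encoder feeds two decoders:

* a **generation decoder** trained adversarially (conditional least-squares
  patch critic) to synthesize two grayscale marker channels — one bright on
  marker-positive nuclei, one on marker-negative nuclei — from the RGB tile;
* a **segmentation decoder** that predicts a per-pixel background/nucleus
  distribution, consuming the generation branch's features at every
  resolution level.

Per-instance marker class is assigned after segmentation by comparing the
mean predicted positive vs negative marker intensity over each extracted
instance (ties go to negative).  The coupling between the branches runs
through three operators:

**Multi-scale dilated block (MDE).**  Every encoder level is a block of
parallel bias-free dilated 3×3 convolutions (default rates 1, 2, 4) with a
rectifier, channel-concatenated, projected back to the level width by a 1×1
convolution, reweighted by a squeeze-and-excitation channel gate
(pool → bottleneck → logistic), and added residually to the input:
`F~ = F* ⊙ γ(F*) + F`.  The branch stage is positively homogeneous (no bias,
no normalization inside a branch); instance normalization sits between
blocks.  With one branch at rate 1 and the gate disabled the block is
exactly a plain residual conv unit, which is the corresponding ablation.

**Gated fusion with adversarial consistency (TRADESGate).**  At each
segmentation-decoder level a single-channel gate
`g = logistic(1×1 conv [f_m ; f_a])` mixes the main stream `f_m` and the
same-scale auxiliary feature `f_a` as a spatially varying convex
combination `f = g f_m + (1−g) f_a`.  Two regularizers act on the gate: an
anisotropic total-variation penalty (mean form by default; the sum form is
exposed) and a prediction-consistency term `KL(p(f) ‖ p(f~))`, where `f~` is
the fusion state under the worst-case gate perturbation found by projected
sign-gradient ascent in an ∞-norm ball of radius ε on the squashed [0,1]
gate scale.  The perturbation never touches the input image or backbone
features, and the search runs with all network parameters frozen.

**FiLM-modulated skips with adversarial consistency (ATFiLM).**  Encoder
skips are modulated channel-wise, `s'[c] = γ[c]·s[c] + β[c]`, with (γ, β)
inferred from the pooled same-scale auxiliary feature through a two-layer
conditioner.  γ is parameterized as `1 + tanh(raw)` and the conditioner's
output layer is zero-initialized, so the untrained pathway is bit-for-bit a
plain skip connection — auxiliary cues modulate rather than override
morphology.  A second KL consistency term penalizes prediction change under
bounded (γ, β) perturbations found the same way.

### A note on the inner maximization

The KL objective is exactly minimized at the clean state, so its gradient
there is zero and a zero-initialized ascent would never move.  The search
therefore starts from a small seeded random perturbation (scale 1e-3,
clipped to the ε-ball), the standard remedy for this degeneracy in
consistency-regularized adversarial training.  The fixed seed keeps training
steps reproducible.

## Losses and optimization

Alternating updates per mini-batch, each touching exactly one block of the
parameter partition {encoder, generation decoder, segmentation decoder,
gates, FiLM conditioners, discriminator}:

1. **Discriminator**: least-squares patch objective on (image, real marker
   channels) vs (image, generated channels).
2. **Generator** (encoder + generation decoder):
   `L_adv + λ_rec L_rec + λ_perc L_perc` with `L_rec` the mean absolute
   error to the marker targets and `L_perc` the mean squared distance
   between features of a fixed, seeded, randomly initialized 3-layer conv
   encoder (no pretrained weights are required at desk scale; a learned
   backbone could be substituted but is deliberately not a dependency).
3. **Segmentation pathway** (segmentation decoder + gates + conditioners):
   `L_seg + λ_cons (L_cons_gate + L_cons_film) + λ_tv L_tv`, with `L_seg`
   cross-entropy + soft Dice in equal weights.  Clean and perturbed
   predictions come from the same forward pass; the gate and FiLM searches
   are run independently and their KL terms summed.

Defaults: AdamW, lr 2e-4, λ_rec 100 (conditional-translation convention),
λ_perc 1, λ_cons 1, λ_tv 1e-4, ε 0.03 with a single ascent step of size ε,
batch size 4.  A warm-up fraction (default 0.2) of the schedule runs
generation-only, so segmentation starts on already-informative auxiliary
features.  Only a constant learning rate is implemented.

Everything runs on a small numpy reverse-mode autodiff core written for
this package (`mscfnet.nn`): float32, im2col/BLAS convolutions with stride
and dilation, a fused instance-norm primitive, and graph pruning so frozen
parameters cost nothing in the backward pass.  Training is single-threaded
deterministic: all randomness flows from per-run integer seeds.

## Synthetic data

The simulator emulates the structure this method assumes in real Ki-67 IHC
tiles: densely packed elliptical nuclei of two classes on a textured
background.  Per tile it rejection-samples `n_nuclei` ellipses (uniform
center, semi-major axis 4–8 px at tile 64, eccentricity 0–0.6, orientation);
a configurable fraction of nuclei is exempt from the minimum
center-distance test and may touch or overlap (overlaps resolve to one
instance id per pixel; layouts where an instance is engulfed entirely are
re-drawn).  Marker-positive nuclei (count = round(positive_fraction · n))
render DAB-brown, negative ones hematoxylin-blue, shaded by a smooth radial
profile; the same profile, masked per class, forms the two clean auxiliary
marker targets.  Per-tile channel-gain stain jitter and additive Gaussian
noise corrupt the image only; targets and labels stay clean.  Identical
parameters (including seed) give bit-identical samples.

What it does **not** model: chromogen co-localization and color deconvolution
physics, scanner PSF/compression, out-of-focus tissue, stromal structures,
or realistic marker-intensity statistics of multiplex immunofluorescence —
the radial profile is a stand-in.  Passing the desk-scale tests therefore
demonstrates that the architecture, losses and optimization behave as
specified, not that the reported metric levels transfer to clinical data.

## Desk-scale study conditions

The harness in `mscfnet.experiments` trains the test-scale network
(depth 3, base width 8, 2-layer width-16 critic) on 32 train / 8 validation
tiles of 64×64 px with ~12 nuclei (30 % positive), for 300 alternating
steps with a 60-step generation-only warm-up, flip-only augmentation, and
evaluates Dice/IoU/PixAcc/AJI (overall and per marker class) and the
positivity-index difference on the held-out tiles.  These sizes were chosen
so a full run completes in minutes on one CPU core.  The full-scale
configuration (depth 4, base width 32, 512-px tiles) is available through
the same config schema.

## Metric conventions

All conventions are fixed in `mscfnet.metrics` for reproducibility:
empty-vs-empty masks score 1 (Dice, IoU, AJI); empty prediction against
nonempty truth scores 0.  AJI matches each ground-truth instance (ascending
id) to the unused predicted instance of maximal pairwise IoU, ties to the
lowest predicted id, each prediction used at most once, unmatched
predictions added to the pooled union.  The per-class AJI restricts both
maps to one marker class before pooling.  The IHC quantification difference
is concretized as the absolute difference of positivity indices (fraction
of marker-positive instances, the Ki-67 index); a prediction with no
instances has index 0.  Dice/IoU/PixAcc are computed on foreground masks
(not class-averaged), per image, then averaged.  Instance extraction
thresholds the nucleus probability at 0.5, labels 8-connected components
(4-connectivity exposed), and drops components under 10 px at 64-px tiles
(the cutoff scales quadratically with tile size).

## Known limitations

* The segmentation head is strictly binary; marker class is assigned
  post-hoc from the generated channels.  A 3-class head is a config stub.
* γ, β are spatially constant per channel; spatially varying modulation is
  out of scope.
* The numpy core is CPU-only and unbatched across devices; full-scale
  (512 px, depth 4) training is possible but slow.
* Small validation splits make per-class AJI and the positivity difference
  noisy; seeds change them by several points.
* At desk scale (32 training tiles, 300 steps) the seed-to-seed spread of
  validation Dice (roughly 0.80–0.96) is larger than the effect of swapping
  any single architectural component, so the single-modification variant
  comparison is reported as a direction, not asserted: distinguishing
  component contributions requires the full-scale setting.
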