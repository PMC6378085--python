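# Methods

`isvseg` segments the intersegmental vessels (ISVs) of zebrafish-embryo
trunk vasculature in 2-D fluorescence projections. This note documents the
model, the objective, the training protocol, the synthetic phantom world the
package is exercised on, and the numerical and design choices that were
genuinely open.

## The segmentation problem

A confocal stack of a fluorescently labelled zebrafish trunk is projected to
a 2-D grayscale frame. The vasculature is ladder-like: the dorsal aorta (DA)
and the dorsal longitudinal anastomotic vessel (DLAV) run horizontally, and
near-vertical ISVs connect them in left/right pairs. In projection the two
vessels of a pair overlap; the vessel closer to the objective (the
foreground vessel, FV) keeps its complete shape, while its contralateral
partner (BV) appears dimmer and partly occluded. The target is the
foreground ISV region only. Two properties make this hard: fluorescence
intensity is uneven along a vessel, and FV/BV overlaps locally have the same
intensity. Abnormal morphologies — short (arrested) vessels, irregular
branches, adhesions bridging neighbours — must still be segmented.

## Network

The model is a *dual residual U-Net*: two encoder–decoder sub-networks
bridged level-by-level.

* **Units.** Every convolutional block is a full pre-activation residual
  unit, `x + F(x)` with `F = BN → ReLU → 3×3 conv → BN → ReLU → 3×3 conv`
  (zero padding preserves spatial size). A 1×1 convolution projects the
  identity path when the channel count changes.
* **Per sub-network layout.** Encoder levels, one bottleneck unit, decoder
  levels. Downsampling is 2×2 max pooling with stride 2; each encoder unit
  doubles the channels. Upsampling is a 2×2 stride-2 transposed convolution
  halving the channels, followed by BN and ReLU. Encoder-to-decoder skips
  are element-wise additions.
* **Variants.** The unit total names the variant: `dual_resunet_14` (the
  default) uses 7 units per sub-network (3 encoder + bottleneck + 3
  decoder); `dual_resunet_10` uses 2+1+2 and `dual_resunet_18` 4+1+4. Only
  the totals are canonical; the symmetric split is this package's choice.
  `dual_unet_14` swaps residual units for plain double-convolution blocks,
  and `single_resunet` drops the second sub-network.
* **Bridging.** Each decoder level of network 1 is concatenated channel-wise
  into the same-resolution encoder level of network 2, then a 1×1
  convolution restores the channel count the encoder unit expects, so the
  second network's units are structurally identical to the first's. Which
  decoder level feeds which encoder level is fixed by resolution; this
  same-resolution pairing is an interpretation (the bridged pairs are not
  uniquely pinned down by the architecture description).
* **Head.** A final 1×1 convolution to two channels and an element-wise
  sigmoid yield two per-pixel probability maps (ISV, non-ISV). The two maps
  are independent sigmoids, not a softmax; the decision rule is explicit: a
  pixel is ISV iff its ISV probability strictly exceeds the non-ISV
  probability (ties → non-ISV).
* **Fusion head (optional, off by default).** Multi-level response maps can
  be bilinearly upsampled to input resolution and combined with per-level
  scalar weights into an auxiliary prediction map. It is provided as an
  option but is not wired into the objective.

`base_channels` defaults to 32 and scales the whole channel ladder; the
tests and the acceptance run use 4 so everything fits a single CPU. Inputs
must be divisible by `2^depth` (8 for the 14-unit variant).

The network, and everything differentiable around it, runs on a small
reverse-mode autodiff core (`isvseg.nn`) written on NumPy float64 arrays:
im2col convolutions, einsum transposed convolutions, reshaping max-pool,
batch normalization with exact train-mode backward, and SGD/Adam
optimizers. Its gradients are verified against central differences in the
test suite.

## Objective

Let `y` be the predicted ISV probability map, `t` the binary ground truth.
All probabilities are clamped to `[ε, 1−ε]`, `ε = 1e-7`, before a logarithm,
so every term is finite and non-negative.

* **Weighted cross-entropy** `L_wce` — pixel mean of
  `−[w·t·log y + (1−t)·log(1−y)]` with a positive-class weight `w`
  (default 1). This is the "plain" arm of the ablation.
* **Contour-aware term** `L_c` — cross-entropy concentrated on two thin
  bands around the ground-truth boundary. With an 8-connected structuring
  element and band width `band_width` (default 2 px), the *inner* band I⁻
  is the erosion residue (object pixels near background) and the *outer*
  band I⁺ the dilation residue. The default form is class-balanced
  cross-entropy restricted to the band,

      L_c = [ −(|I⁺|/|I|) Σ_{p∈I⁻} log y_p − (|I⁻|/|I|) Σ_{p∈I⁺} log(1−y_p) ] / |I|,

  each side weighted by the opposite band's share so neither side of a thick
  vessel dominates. The pairing of weights with sums is not uniquely
  determined by the formulation this implements; `swap_band_weights`
  transposes it, and `mode="emphasis"` instead applies the band indicator as
  an additive weight (1 inside the band, doubling its contribution) over
  full-image cross-entropy. Masks without a boundary (all-zero/all-one) have
  empty bands; the term then falls back to `L_wce` and the fallback is
  flagged in the loss breakdown.
* **Shape-constraint term** `L_s` — the per-pixel negative log-score of the
  correct class, averaged over pixels, with the two sigmoid outputs
  normalized into class scores `(y, y') / (y + y')` first. The
  normalization is essential: with two independent sigmoids the
  unnormalized penalty has a trivial global minimum at "both channels 1
  everywhere", which carries no shape information (we observed exactly this
  collapse). The normalized term is `log 2` per pixel at a uniform 0.5
  prediction, vanishes at the ground truth, and decreases strictly along
  the linear blend between the two — the property that makes it a useful
  learning signal for junction regions (ISV–DA, ISV–DLAV) that the contour
  band does not cover.
* **Combined objective.** `L = L_c + L_s`. The four ablation arms are
  `wce`, `c`, `s`, `s+c`; the single-term arms are exactly the named terms.
  Weight decay (5×10⁻⁴) is an L2 penalty applied through the optimizer and
  never added to reported loss values.

`L_s` is normalized per pixel (rather than summed per image) so `L_c` and
`L_s` live on comparable scales; the per-image alternative only rescales
the gradient.

## Data pipeline

Full frames are cut into one training patch per ISV pair:

1. **Adaptive cropping.** Connected components of the vessel annotation are
   sorted by centroid column and grouped into consecutive pairs (a trailing
   unpaired component gets its own crop). Crops aim at a height of 120–160
   px on full-scale data (smaller bounds are used for the small phantom
   frames), clipped to the frame and never cutting the pair. The crop's
   stored mask keeps only its own pair's pixels; optionally a separate
   label mask (e.g. foreground-only) provides the training target while the
   all-vessel mask drives the geometry.
2. **Zero-padding to square**, content centered.
3. **Mirror/flip augmentation** — the 4-element group {identity, horizontal
   mirror, vertical flip, both}, multiplying the patch count by exactly 4
   (6842 source patches → 27368).
4. **Resizing** to the training side (128 px by default): bilinear for
   images, nearest-neighbour plus re-binarization for masks, so masks stay
   exactly binary.

Splits are five independent seeded 60/20/20 train/test/validation
re-splits. (A single 60/20/20 split and "five cross-validation sessions"
cannot both hold literally; the five seeded re-splits reading keeps both
numbers.)

## Training protocol

Weights are initialized from a Gaussian; the standard deviation uses He
scaling `sqrt(2 / fan_in)`, suited to ReLU stacks. The optimizer is SGD
with momentum 0.9 and weight decay 5×10⁻⁴ (the classical choice consistent
with an explicit learning-rate-halving schedule); Adam is available through
the config and is what the small-budget overfit fixtures use, since SGD
needs far more steps at that scale. The initial learning rate is 0.001.

The schedule operates on per-epoch mean training loss. The mean of the
first 10 epochs is frozen as the *baseline*; afterwards the learning rate
is halved whenever the improvement over the previous epoch is below 1% of
the baseline. Training stops when the relative difference of consecutive
epoch losses falls below 1e-4 or at 150 epochs. Validation loss, when a
validation set is supplied, selects the checkpoint restored at the end and
nothing else. Non-finite losses abort with a diagnostic naming the epoch
and term. With seeded shuffling and deterministic kernels, identical
configs reproduce identical loss histories bit for bit.

## Synthetic phantoms

The real dataset behind the method is not public, so the package ships a
generator of fluorescent-vessel phantoms that emulates the structure the
method must handle, with exact ground truth:

* two horizontal rails (DA bottom, DLAV top) rendered as image context but
  excluded from the foreground mask;
* `n_isv_pairs` near-vertical ISVs with jittered centerlines; each pair may
  add a dimmer background partner (probability `background_vessel_prob`,
  default 0.7) drawn *before* the foreground so foreground occludes it;
* abnormal morphologies with probability `p_abnormal` (default 0.2),
  uniformly among short, branching and adhesion;
* brightness = per-vessel gain × a low-frequency sinusoid along the
  centerline with amplitude `intensity_unevenness` (default 0.3);
* additive Gaussian noise (`noise_sigma`, default 0.02) clipped to [0, 1].

Vessels are rasterized as thick polylines (a pixel is inside when its
center is within half the stroke width of the centerline); masks are
rasterized without anti-aliasing so ground truth is exact, images with a
soft 1-px edge. A single master seed drives everything; sample *i* of a
dataset uses seed `master + i`, so manifests are reproducible
bit-identically across runs and platforms. The geometric defaults (stroke
width 3 px, rail positions at 15%/85% of the height, pair spacing ≥ 20 px)
were chosen once for visual plausibility; no quantitative morphology
statistics exist to calibrate against, so passing tests demonstrate correct
mechanics and learnability on this world, not clinical fidelity.
Specifically absent from the phantom world: 3-D projection artifacts,
point-spread blur, autofluorescence background, parachordal vessels beyond
an optional distractor, and annotation noise.

## Evaluation

All metrics are computed per image and then aggregated as median / mean /
sample standard deviation (ddof = 1), never micro-averaged over pooled
pixels. Accuracy is `(TP+TN)/(TP+TN+FP+FN)` on the 0–100 scale; Dice is
`2TP/(2TP+FN+FP)`, with the empty-vs-empty case defined (and flagged) as
1.0. PR and ROC curves sweep 256 evenly spaced thresholds plus the set of
distinct scores when the input has ≤ 10⁴ pixels, making the curves exact on
small inputs; AUC is trapezoidal, with ROC anchored at (0,0) and (1,1).
Degenerate ground truth (one class only) drops the undefined points and
reports how many. The paired t-test on per-image metric differences is
two-sided at the 5% level, with explicit zero-variance branches (all-zero
differences → p = 1; constant non-zero differences → the exact-t limit,
flagged). Qualitative overlays paint TP red, FP blue, FN yellow over the
grayscale base, so tint-class counts equal the confusion tallies exactly.

## Problem sizes used by the tests and the acceptance run

The shipped runs use deliberately small instances: phantoms of 64×112 with
two ISV pairs, patch side 64, `base_channels=4`, eight training patches for
the memorization check and 12-train/6-test frames for the held-out run.
These sizes exercise every code path of the full-scale configuration (which
is a matter of `base_channels`, patch side and epoch count) while keeping a
complete run in minutes on one CPU.

## Known limitations

* The phantom world is a geometric caricature; held-out phantom Dice says
  nothing quantitative about microscope data.
* The contour term's printed formulation is ambiguous in two places (the
  role of the band indicator, the weight/sum pairing); both readings are
  implemented but the default is a choice, not a derivation.
* The autodiff core supports exactly the operations this architecture
  needs; it is not a general-purpose framework, and it is CPU-bound — the
  full-scale 128×128 / base-32 configuration trains, but slowly.
* Batch-norm running statistics make evaluation-mode outputs depend on the
  training history; all determinism contracts are stated for evaluation
  mode.
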