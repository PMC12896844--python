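# Methods

This note documents the models, conventions, and numerical choices behind
`ccw`, in the spirit of the methods documentation that mature scientific
packages ship alongside their code.

## Problem setting

The package estimates chicken carcass weight from multi-view RGB images in
two stages. First, a semantic segmentation network partitions each image
into background, torso, head, and leg pixels. Second, per-part pixel counts
are converted to physical areas with a known pixel-per-centimetre
calibration and regressed against weight. The study design the package
emulates is a cohort of 301 carcasses, each photographed from three
standardized views (ventral, dorsal, lateral) with three replicate captures
per view — 2709 images — split 8:1:1 **at the carcass level** so that no
animal contributes images to more than one subset.

## Segmentation network

The network is an encoder-decoder U-Net whose convolutional units are
**recurrent-residual blocks**: a feed-forward 3×3 convolution produces an
activation `a = BN(conv_ff(x))`, which a shared recurrent 3×3 convolution
then refines `t` times,

    y_0 = relu(a),   y_s = relu(a + BN(conv_rec(y_{s-1}))),  s = 1..t,

two such layers are stacked, and the block output adds a shortcut (identity
when channel counts match, a 1×1 convolution + batch norm otherwise).
`t = 2` by default.

Two attention operators augment the backbone:

* **Selective-kernel (SK) attention** after every encoder block. Two
  branches convolve with 3×3 and 5×5 kernels (each followed by batch norm
  and ReLU), their sum is globally average-pooled per channel, compressed by
  a fully connected layer with batch norm and ReLU to `d = max(C/r, 4)`
  units, expanded into one logit vector per branch, and softmax-normalized
  across branches. The output is the per-channel convex combination
  `V = a·U1 + b·U2` with `a + b = 1`. Exactly two branches are supported;
  the softmax-pair formulation does not generalize unchanged beyond two.

* **CBAM** on each skip connection before decoder concatenation. The
  channel gate is `σ(MLP(avgpool F) + MLP(maxpool F))` with a shared,
  bias-free two-layer perceptron (reduction `r`, ReLU in between); the
  spatial gate stacks the per-pixel channel mean and channel max, convolves
  with a bias-free 7×7 kernel, and applies a sigmoid. Channel gating is
  applied first, then spatial gating, following the original CBAM design.
  Because every gate lies in (0, 1), the module never increases the
  magnitude of any feature element — a property the test suite asserts.

The decoder upsamples with 2×2 stride-2 transposed convolutions (chosen
over bilinear interpolation so that every learnable stage enters the
closed-form parameter count the tests verify), concatenates the gated skip,
and applies another recurrent-residual block. A 1×1 convolution head emits
`K` logits per pixel; prediction is the per-pixel argmax.

Production defaults are depth 5, 64 base channels, 640×640 inputs. Tests
and the bundled overfit harness use depth 3 with 8 base channels on 64×64
images, exercising the identical code path at desk scale.

All tensor computation runs on a small reverse-mode automatic
differentiation engine over numpy arrays (`ccw.autodiff`). The engine is
deliberately minimal — float64 throughout, stride-1 same-padding
convolutions, eager evaluation — and every operator's gradient is validated
against central finite differences in the test suite. The attention
operators additionally have independent scalar-loop oracles (written
without the engine) that the vectorized implementations must match to
1e-6.

## Training

The loss is `0.5 · cross-entropy + 0.5 · soft multi-class Dice` (Dice
smoothing ε = 1e-6). The optimizer is Adam with a constant learning rate;
production defaults follow the study configuration (batch 8, 200 epochs,
initial learning rate 0.001, 640×640 inputs). All randomness — weight
initialization, shuffling — derives from the config seed, so identical
runs are bit-identical. Batch normalization uses per-batch statistics during
training and stored running statistics at inference, which is why
single-sample oracle tests run in eval mode.

The **overfit harness** fits a depth-3/base-8 network (both attention
modules on, learning rate 3e-3, batch 4) to eight synthetic 64×64 images.
It reliably drives training mIoU above 0.95 within ~100 optimizer steps on
one CPU; the acceptance suite requires ≥ 0.90 within 300 steps. This
checks that the assembled architecture, loss, and optimizer can actually
learn, which shape tests alone cannot.

## Evaluation metrics

All metrics derive from per-class one-vs-rest pixel confusion counts pooled
over the evaluated images (micro-averaging): IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), precision, recall, and their harmonic mean F1.
mIoU averages IoU over the foreground classes by default — including the
large dark background would inflate the score — with an option to include
it. Degenerate conventions: a class absent from both prediction and ground
truth is excluded from means (its per-class score is reported as 1); a
vanishing denominator with error mass present scores 0. Min-max
normalization `(x − min)/(max − min)` is provided for cross-metric model
comparison displays and raises on constant input rather than guessing.

## Morphometry

Predicted masks are refined per class by a morphological closing (fills
holes smaller than the structuring element) followed by an opening (removes
speckles). The default element is a disk of radius 5 px at 640×640,
scaled proportionally at other resolutions; neither shape nor size is
canonical, so both are configurable. Classes are recomposed under the fixed
priority torso < leg < head so pixels claimed by two classes after dilation
resolve deterministically. Calibration is carried as a known `px_per_cm`
value in the dataset manifest rather than detected from an in-image marker;
marker detection is out of scope. Calibrated area is
`pixels / px_per_cm²`.

## Synthetic data

Because the source imagery is proprietary, the package ships a generator
whose defaults define the study conditions: 301 carcasses × 3 views × 3
replicates, dark background (intensity ~ N(20, σ_tex)) with bright
foreground (~ N(180, σ_tex)), 10 px/cm calibration at 640×640. Shapes are
analytic primitives — torso ellipse, head disc (the bird hangs head-down),
two splayed leg capsules — kept pairwise disjoint so each part has a
closed-form area. A pixel belongs to a part iff its center lies inside the
shape. The 8° leg splay breaks raster axis alignment; perfectly vertical
capsules suffer a systematic column-quantization bias of up to ~2.5% in
pixel area, which the splay reduces below 0.1% at full resolution.

Cohort variation combines a shared size factor `s ~ N(1, 0.12)` (clipped to
[0.75, 1.3]) with independent per-part linear-size multipliers
`~ N(1, 0.05)` (clipped to [0.85, 1.15]). The multipliers mimic
conformation differences between birds and make the per-part areas linearly
independent across the cohort — without them all areas would be exact
multiples of `s²` and the per-part regression coefficients would be
unidentifiable. Replicate captures re-draw a global position jitter
(σ_pos = 2 px), a 1% size jitter, and fresh texture noise.

Weights follow a noisy linear model on per-part areas averaged over views:

    W = β₀ + Σ_p β_p · area_p + N(0, σ_w),

with part weights generated analogously. Defaults
(β₀ = 80 g; β = 2.6, 2.2, 2.4 g/cm² for torso, head, leg) give cohort
weights around 1 kg, plausible for a yellow-feather broiler carcass. The
true area-weight relationship of real carcasses is unknown to this package;
the linear Gaussian form is a modelling stand-in, not a biological claim.
When σ_w is unspecified, the generator calibrates it so the deterministic
area term explains 90% of the cohort weight variance, which puts achievable
test R² in the high-0.8/low-0.9 range typical of this literature.

What the generator does **not** emulate: feathers, viscera, specular
lighting, perspective distortion, occlusion, annotation error. Passing
tests therefore demonstrate that the pipeline machinery is correct and
self-consistent, not that the network would reach any particular accuracy
on real processing-line imagery.

## Regression

Four feature groups ("mods") map areas to weights: Mod1 overall silhouette
area → total weight; Mod2 torso → torso weight; Mod3 head → head weight;
Mod4 leg → leg weight. Each mod has exactly three features — the calibrated
area per view, replicates averaged first. Calibrated cm² (rather than raw
pixels) keeps features commensurate with the weight model's units.

Five regressor families are supported: MLP, RBF-kernel SVR, Bayesian ridge,
LightGBM, and XGBoost gradient boosting. Models fit on the training
carcasses; small fixed hyperparameter grids are selected on validation
RMSE; R² and RMSE are reported once on the held-out test carcasses.
Uncertainty is quantified by a percentile bootstrap (B = 1000 paired
resamples of the test set, seed-fixed) — the CI construction is a package
choice since none is canonical for this design. Outliers are flagged where
|residual| > 2σ, with σ the sample (n−1) residual standard deviation;
σ = 0 yields no flags.

## Problem sizes used by tests and the acceptance script

Oracle suites run on tiny tensors (C ≤ 8, 5×5 maps) and 12×12–15×15 masks.
The training harness uses 8 images at 64×64 and ≤ 300 steps. Cohort-level
checks (split hygiene, regression, calibration) use 301 carcasses at a
320×320 canvas with areas taken from the closed-form geometry, and the
bootstrap coverage simulation uses 200 replicates of n = 80. These sizes
were chosen so the full suite completes in minutes on a single CPU while
still exercising every code path at the study's cohort scale.

## Known limitations

* The autodiff engine is single-threaded numpy; production-scale training
  (640×640, depth 5) is out of reach and out of scope.
* Binary masks only per class; no instance separation or topology analysis.
* The SK operator is fixed at two branches.
* Bootstrap CIs are percentile-based; BCa would have better small-sample
  properties but adds little at n = 30 test carcasses.
* Morphological refinement can erase structures thinner than the element —
  at 64×64 the scaled disk has radius 1 and leg capsules are ~2 px wide, so
  desk-scale area extraction is less faithful than at 320+ canvases.
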