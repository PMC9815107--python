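# Methods

## Model

The classifier stacks a stem convolution (3×3, stride 2), seven mobile
inverted-bottleneck (MBConv) stages in an EfficientNet-B6-shaped layout —
widths (32, 40, 72, 144, 200, 344, 576), repeats (3, 6, 6, 8, 8, 11, 3),
expansion 1 then 6, kernels 3/3/5/3/5/5/3, strides 1/2/2/2/1/2/1, stem 56
and head 2304 channels — followed by a 1×1 head convolution, global average
pooling, and a K-way linear layer. Activations are swish; every convolution
is followed by batch normalization. Squeeze-excitation blocks inside MBConv
are intentionally omitted: channel attention in this design is carried by
CBAM, and doubling up channel gates would confound the ablation between the
plain backbone and the attention-augmented one.

Two attention mechanisms modify the backbone:

* **CBAM** — channel gate first (shared two-layer bottleneck MLP over the
  global max- and average-pooled descriptors, summed before the sigmoid; no
  bias terms; bottleneck width `max(1, C // reduction_ratio)` with ratio 16
  by default), then a spatial gate (channel-wise max and mean maps,
  concatenated, reduced by a single 7×7 convolution, sigmoid). Both gates
  lie strictly in (0, 1), so gating never amplifies and always preserves
  shape. The phrase "before each regularization" admits several placements;
  we place one CBAM per selected stage, in the last block between the
  projection convolution and the projection batch norm. Per-layer insertion
  in every MBConv would multiply parameter count for no drawn benefit. By
  default the selected stages are all stages after the MSFM insertion
  point.

* **MSFM** — after stage 2 (shallow, high-resolution features): CBAM
  recalibration, then three parallel 3×3 dilated convolution branches at
  rates 1, 2, 4, each zero-padded by `r·(k−1)/2` so all branches preserve
  spatial extent, each followed by batch norm + swish; branch outputs are
  concatenated and reduced by a 1×1 convolution (an elementwise-sum fusion
  mode exists behind `fusion="sum"`). Branch and output widths default to
  the input width, making the module drop-in shape-preserving; the MSFM
  output *replaces* the stage-2 stream (single path) rather than being
  summed with it.

Dilated-kernel geometry: the taps of a k×k kernel at rate r span a window
of side `k_d = k + (k−1)(r−1)`; the parameter count (9 per channel pair for
k = 3) is independent of r. An alternative receptive-field expression
`(k+1)(r−1) + k` is provided as `receptive_field_side` for reference but is
deliberately unused: for k = 3, r = 2 it gives 7, which disagrees with the
5-pixel bounding box a single dilated convolution actually covers (the
package verifies the 5 empirically with a delta-image footprint oracle).

## Loss

`FL(p_t) = −a_t (1 − p_t)^γ log(p_t)`, with `CE` the γ = 0 special case.
The identity `FL(γ=0, a=1) = CE` holds exactly and is enforced end-to-end
(scalar forms and full training trajectories). γ defaults to 2 and `a_t` to
inverse-frequency weights `N/(K·n_c)` computed on the training split only;
both are mandatory, logged config entries because no canonical values exist
for them. Probabilities are clamped to `[1e-7, 1]` before the logarithm
(and to `1 − 1e-7` from above inside the differentiable batch loss, keeping
the γ-power's gradient finite), so the loss is never NaN; a clamp on the
scalar path emits a warning. The multiclass form sums the true-class terms;
a printed variant using `log(1 − p_t)` exists in the literature but is a
typographical artifact and is not implemented.

## Data

Ingestion scans a directory-per-class tree lexicographically; unreadable
files go to an exclusion report on the manifest rather than being silently
dropped. The offline augmentation recipe is exactly: 180° rotation, ×0.7
brightness (half-away-from-zero rounding then clipping, declared so results
are bit-stable), horizontal flip — originals plus three provenance-tagged
variants per image. An optional ×1.3 brightening variant exists but is off
in the reference recipe, which enumerates only the decrease. A per-class
cap truncates deterministically (originals first, then whole variant waves
in recipe order). Splits use largest-remainder apportionment of the ratios
(per class when stratified, the default), seeded; 8:1:1 is the default and
90/10 a preset (`NINETY_TEN`). Splitting is designed to run before
augmentation so variants of one photograph never straddle train and test.

### Synthetic generator

Emulates the structure of field-photographed cassava leaf datasets: a
leaf-green background (RGB ≈ (52, 110, 46)) with smooth low-frequency
shading and additive Gaussian pixel noise (sd 6), plus class-specific
lesion motifs with randomized position/count/scale — pale angular blotches
(bacterial-blight-like), elongated brown streaks, small green-on-green
mottle dots, yellow mosaic rectangles, and a motif-free healthy class. All
motif parameters are exposed via `MotifSpec`. Generation is a pure function
of the seed (each image keyed by (seed, class, index)), and images default
to 600×800 to mirror typical source photographs; tests use 64×64 and below.

What the generator does *not* emulate: real leaf geometry and venation,
illumination/pose variation, background clutter, inter-class symptom
overlap, and label noise. Synthetic classes are separable largely by colour
statistics, so passing the training smoke test demonstrates that the
optimization loop, gradients, and data plumbing work — not field-level
accuracy. A guard test checks that a trivial channel-mean nearest-centroid
classifier beats chance, i.e. the generator genuinely carries class signal.

## Training

Defaults: 150 epochs, Adam (β₁ 0.9, β₂ 0.999) at learning rate 1e-4 with no
schedule, batch size 16, focal loss. No early stopping; when a validation
split is supplied, the best-validation-accuracy weights are restored at the
end. A non-finite loss aborts with the offending epoch. Preprocessing
resizes bilinearly to the configured resolution, scales to [0, 1], and
standardizes with per-channel mean/std computed from the training split
(ImageNet constants behind a flag; the stats are stored in the checkpoint
sidecar so inference and explanation reuse them). Runs are fully seeded —
initialization, batch order, and statistics derive from the config seed —
and are bit-reproducible on one platform.

### Problem sizes used in tests

The test and acceptance suites run a scaled-down configuration chosen as a
CPU-scale study system: `tiny_config()` = width multiplier 0.1, depth
multiplier 0.12 (one block per stage), 64×64 inputs. The smoke-training
check uses 50 images/class at 64×64, batch 16, Adam at 1e-3 (a standard
rate for small from-scratch models), 30 epochs. Structural shape checks
run the width-0.1 model at full B6 depth.

## Evaluation

Confusion matrix with rows = true and columns = predicted, stated in every
output. Per-class precision, recall, and one-vs-rest accuracy; overall
accuracy = trace/total. Zero denominators yield a 0 sentinel plus an
`undefined` flag, never NaN. Micro-averaged precision and recall equal
overall accuracy for single-label multiclass data; this identity is
asserted over random matrices as an internal consistency check, and the
counts are cross-checked against scikit-learn in the test suite.
Percentages are presentation-only; internal values are fractions.

## Explanation

Grad-CAM: gradients of the target-class logit with respect to a captured
layer's activations, spatially averaged into channel weights; the weighted
channel sum is rectified, bilinearly upsampled, and min-max normalized to
[0, 1]. The default layer is the MSFM output. A constant raw map returns
all-zeros with a `constant` flag rather than dividing by zero. Overlays
alpha-blend a colormapped heatmap (default "jet", recorded in the output's
JSON metadata) onto the image; a comparison-grid helper renders
original | baseline | MSFM panels side by side.

## Numerical choices and implementation notes

* The network stack is a numpy reverse-mode autograd (`msfnet.nn`):
  float32 throughout, convolutions via im2col/col2im with stride, dilation,
  and groups (depthwise = groups = channels). Convolutions are verified
  against scipy correlation oracles and finite differences; tied maxima in
  max reductions share the gradient equally.
* Batch norm uses eps 1e-5 and momentum 0.1 running statistics; zero-input
  maps stay zero through normalization because β initializes to 0.
* Checkpoints are `.npz` weight archives with a JSON architecture sidecar;
  the sidecar alone reconstructs the model.
* Width scaling floors channels at 1 (`max(1, round(c·m))`) and depth at
  one block per stage, so arbitrarily small multipliers remain valid.

## Known limitations

* No pretrained weights; full-resolution B6 training is out of reach of a
  CPU-only stack, so reported behaviours are for scaled-down models on
  synthetic data.
* The CBAM placement ambiguity noted above means other placements (e.g.
  inside every block) are plausible designs; the chosen one is fixed and
  configurable per stage, not searched.
* Single-process, single-device training only; no mixed precision, no
  learning-rate schedules, no label smoothing or mixup.
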