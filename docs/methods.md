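# Methods

## The detector and its assumptions

`avidet` assembles an anchor-free one-stage detector in the familiar
backbone / neck / head decomposition. The baseline is the standard nano
configuration of that family: a C2f/SPPF backbone (depth multiplier 0.33,
width multiplier 0.25, giving stage widths 16/32/64/128/256), a PAN neck
over strides 8/16/32, and decoupled per-level heads that predict class
logits and a discrete distribution over `reg_max = 16` bins for each of the
four box distances (left/top/right/bottom, in stride units); the box is the
softmax expectation of that distribution. With 5 classes this baseline has
3,011,807 trainable parameters and costs 8.1 GFLOPs at a 640 x 640 input
under the FLOP convention below.

Four independent switches modify it:

* **`rfaconv`** replaces the backbone's four strided downsampling
  convolutions (not the stem) with receptive-field attention convolutions.
  Each input channel expands into k^2 = 9 receptive-field slots via a
  grouped 3 x 3 convolution (groups = channels, so each channel owns its
  slots); an attention branch average-pools over the same window, mixes
  information with a grouped 1 x 1 convolution and softmax-normalizes
  *across the nine slots of each channel* (not across channels). The
  weighted slots are tiled into a 3x-larger map and fused by a stride-3
  convolution, so the block is a drop-in replacement spatially.
  "Norm" in the feature branch is batch normalization over the expanded
  C*k^2 channels.
* **`dyasf_p2`** swaps the PAN neck for the DyASF-P2 neck described below.
* **`lsdecd`** swaps the per-level heads for the shared detail-enhanced
  head.
* the box-regression loss is chosen by name from
  {`ciou`, `shape_iou`, `inner_iou`, `inner_shape_iou`}.

Training keeps the baseline composite loss structure — BCE classification
against task-aligned soft targets, the selected IoU-family box loss, and a
distribution-focal term — with weights 7.5 / 0.5 / 1.5 (box / cls / dfl).
Task-aligned assignment (alignment metric `score^0.5 * IoU^6`, top-10
candidate anchors inside each ground-truth box, ties resolved by IoU) is
treated as infrastructure, not a contribution; only the IoU term of the box
loss changes between variants. The optimizer is plain SGD with momentum
0.937 and weight decay 5e-4; augmentation is deliberately absent because
the package's purpose is component verification, not leaderboard training.

## The loss family

All losses operate on corner-format boxes and are differentiable end to end
(the training loop backpropagates through the DFL expectation into them).

* `IoU`: intersection over union; degenerate zero-area overlap counts as 0.
* `CIoU`: `1 - IoU + rho^2/c^2 + alpha v`, `v` the standard aspect term
  `4/pi^2 (atan(w_gt/h_gt) - atan(w/h))^2`. `alpha = v / (1 - IoU + v)` is
  differentiated through rather than held constant; this keeps analytic and
  numerical gradients consistent and changes the loss value not at all.
* `Shape-IoU`: the ground-truth box's aspect enters through
  `ww = 2 w_gt^s / (w_gt^s + h_gt^s)` and `hh` (their sum is exactly 2 for
  every box and every exponent `s = scale`); the center-distance term pairs
  `hh` with the x-offset and `ww` with the y-offset (as in the cited
  original), normalized by `c^2`, the squared diagonal of the minimal
  enclosing box — the standard DIoU-family normalizer. The shape cost uses
  absolute relative size differences inside the exponential and raises
  `(1 - e^{-.})` to `theta`.
* `Inner-IoU`: auxiliary boxes scaled by `ratio` about each box's own
  center. The auxiliary corners are computed by corner interpolation
  (`x1 (1+r)/2 + x2 (1-r)/2`), algebraically identical to
  `center -/+ r*size/2` but exact at `r = 1`, so Inner-IoU then equals IoU
  bitwise and Inner-ShapeIoU collapses to Shape-IoU with error exactly 0.
* `Inner-ShapeIoU`: `L_Shape + (IoU - IoU_inner)`.

Defaults are neutral: `scale = 0` (making `ww = hh = 1`), `theta = 4`,
`ratio = 1`. No tuned values are claimed for them; all three are exposed in
the training config.

## The DyASF-P2 neck

Wiring (resolutions quoted at 640 input):

* stride 16: TFE(P3, P4, P5) -> C2f -> N4 (40 x 40);
* stride 8: TFE(P2, P3, P4) -> C2f, plus SSFF(P5, P4, P3) added in -> N3;
* stride 4: DySample(N3) concat P2 -> C2f, refined by adding
  SSFF(N4, N3, N2) -> N2 (160 x 160);
* strides 8/16/32 head inputs come from a PAN-style downward path over
  N3, N4 and P5.

That uses exactly two TFE and two dynamic-SSFF blocks plus the P2 level.
Design details:

* **DySample**: a 1 x 1 convolution predicts one (dx, dy) per output pixel
  per channel group (4 groups), scaled by a 0.25-cell scope; sampling is
  bilinear at half-pixel grid + offset, with border clamping. The offset
  predictor starts near zero, so the module begins as bilinear upsampling
  (a regression-tested contract).
* **SSFF**: deeper levels are 1 x 1-aligned to the fusion width, dynamically
  upsampled to the reference level, smoothed with a normalized Gaussian,
  stacked along a new scale axis, and reduced by a 3-D convolution with
  kernel (3, 1, 1) (stored flattened as an equivalent 1 x 1 convolution
  over the stacked channels) followed by BN + SiLU. `sigma = 1.0` per level
  (kernel radius `ceil(2 sigma)`), configurable; smoothing uses reflect
  padding so constants are preserved exactly.
* **TFE**: branch widths are aligned by 1 x 1 convolutions to the medium
  level; the large branch is downsampled by the element-wise mean of 2 x 2
  max- and average-pooling (one tensor, fixed width — the simplest reading
  of "combining" the two poolings); the small branch is upsampled by
  nearest neighbour; outputs concatenate to 3 x width channels.

The neck's channel plan is not dictated by the architecture family, so it
is a design choice of this package: output widths (80, 64, 96, 128) for
strides (4, 8, 16, 32), TFE branch widths 128 (deep) and 80 (shallow), and
a stride-8 trunk width of 84, chosen so that the full five-class variant
meets its published budget of 2.2 M parameters and 12.1 GFLOPs at 640.
Widths scale linearly with the model's width multiplier (rounded to
multiples of 4 so grouped offsets stay valid).

## The shared detail-enhanced head

Each level is projected by a level-specific 1 x 1 convolution + group
normalization to a shared width (default 24 at nano scale — the lightweight
end of the design space, chosen to meet the 2.3 M-parameter budget of the
head-swapped five-class variant). Two *shared* DEConv+GN+SiLU blocks then
process every level with one parameter set, followed by shared 1 x 1
classification and regression convolutions; a per-level learnable scalar
(initialized at 1) multiplies the regression feature map to absorb
per-stride scale statistics.

DEConv sums five parallel 3 x 3 banks whose effective kernels are linear
tap transforms of the stored weights:

* vanilla: `e = w`;
* central difference: `e = w`, then `e[1,1] -= sum(w)` (the interior
  response to a constant is exactly zero);
* angular difference: `e = w - rot(w)`, the eight outer taps cycled one
  step clockwise, center fixed;
* horizontal difference: `e = w - rowmean(w)` — every row of `e` sums to
  zero, so horizontally flat signals are annihilated;
* vertical difference: `e = w - colmean(w)`.

All transforms are linear, so the five branches fuse exactly into a single
3 x 3 kernel (`deconv_fuse`); branch-sum and fused outputs agree to float32
round-off, before and after training steps. Group normalization uses 16
groups (or the channel count if smaller).

## Evaluation conventions

AP integrates the precision envelope on the 101-point recall grid
0, 0.01, ..., 1 (the de-facto standard rule; exact all-point interpolation
is available behind a flag). mAP@0.5:0.95 averages the per-class AP over
IoU thresholds 0.50 : 0.05 : 0.95. Matching is greedy in confidence order;
each detection claims the highest-IoU unmatched ground truth of its class
in its image. Scalar precision/recall per class are read off at the
confidence maximizing F1 on the IoU-0.5 PR curve, since a scalar operating
point must otherwise be arbitrary. The confusion matrix matches
class-agnostically (defaults: confidence 0.25, IoU 0.45, both
configurable), is indexed [predicted, true] with background last, counts
missed ground truths in the background row and spurious detections in the
background column, and normalizes per true-class column.

## FLOP and parameter accounting

Parameters are the exact count of trainable scalars. FLOPs are counted as
2 x multiply-accumulate summed over convolution and affine weight
applications only — pooling, normalization, activations and interpolation
are not counted — during a real forward pass at the stated input size.
Conventions differ between tools by up to ~10%; this one is stated
prominently because the package's cost figures are only meaningful under
it. FLOPs under this convention scale exactly with input area, which the
cost tests exploit.

## The synthetic scene generator

The generator emulates the *structure* of wetland surveillance data — five
target classes, many small targets per frame, partial occlusion, large
scale variation, low-contrast clutter — with shape/hue-coded ellipses,
triangles, rectangles, crosses and crescents on a textured background; the
last class is pale and low-saturation, mimicking white birds against bright
water. Object scales are sampled log-uniformly; a configurable fraction of
objects is placed in constructively overlapping pairs; boxes are tight to
the rendered mask, clipped to the image, and written normalized in YOLO
format. Scene i of a dataset derives its RNG from `seed + i`, so datasets
are reproducible image by image, and splits follow the floor-then-assign
7:2:1 convention (leftovers go to val, then test).

What it does *not* emulate: photographic texture, lighting and weather,
motion blur, inter-class visual similarity, or annotation noise. Tests
passing on these scenes therefore demonstrate that the components are
implemented correctly and that the assembled detector can learn — they say
nothing about accuracy on real surveillance footage.

## Desk-scale problem sizes

The end-to-end learnability check trains a reduced full variant (width
multiplier 0.125, shared head width 16, `reg_max` 8) on 96 x 96 scenes with
1-3 large, well-separated objects: 105 training / 30 validation images, 15
epochs, batch 8, SGD lr 0.02, fixed seeds throughout. These sizes are the
package's chosen verification scale: large enough that mAP@0.5 reliably
exceeds the 0.5 self-consistency bar (0.58 on the shipped configuration),
small enough to run in minutes on one CPU core. The single-batch overfit
check runs 30 iterations on 8 fixed images.

## Numerical choices and degenerate inputs

* Engine tensors are float32; the loss-family scalar API computes in
  float64 (gradient checks perturb at 1e-6, below float32 resolution).
* IoU denominators carry an epsilon of 1e-9 in the batched training path
  and 0 in the scalar API (valid boxes cannot produce a zero union).
* Softmax subtracts the row maximum; BCE-with-logits and log-softmax use
  the standard overflow-free forms; sigmoid is branch-stable.
* Boxes with non-positive width or height are rejected with a dedicated
  error; `ratio` outside [0.5, 1.5], `theta <= 0`, `scale < 0`,
  `sigma <= 0` and upsampling factors < 2 likewise.
* Anchor-free decoding clamps DFL distances to [0, reg_max - 1]; target
  distances are clipped just inside the top bin before building the
  two-hot DFL targets.
* Classification biases start at the ~1% prior and regression biases at 1,
  the usual stabilization for sparse-object detection training.
* Training is deterministic given the seed: parameter initialization,
  batch order and every forward/backward are pure numpy with no
  run-to-run variation; two builds from the same seed produce bit-identical
  forward passes (regression-tested).

## Known limitations

* The numpy training loop is a reference implementation: correct,
  deterministic and slow. Full-resolution (640) training is out of its
  intended range; component verification and reduced-scale training are in.
* The training-time data path assumes square images of the configured size
  (the generator produces exactly that); arbitrary aspect ratios would need
  letterboxing.
* BatchNorm statistics are per-batch without momentum warmup; very small
  batches at eval-scale widths can make eval-mode outputs noisy early in
  training (evaluation here runs after training completes).
* The confusion matrix uses single-threshold greedy matching; it is a
  diagnostic, not a scoring metric.
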